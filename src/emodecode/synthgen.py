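"""Synthetic ROI-level EEG with planted condition effects.

Generates cohorts that emulate a within-subject music-performance study:
each trial pairs a 30 s neutral-baseline segment with a 30 s emotional
segment, recorded over ten scalp ROIs at 500 Hz, under five expressed
emotions (distressed, excited, depressed, relaxed, neutral).

Each ROI signal is a sum over the five EEG sub-bands of band-limited
Gaussian noise.  Condition effects are planted through three orthogonal
mechanisms so every downstream feature family has known ground truth:

* band-power gains — per (condition, band, ROI) amplitude multipliers;
* shared-source couplings — a latent band-limited source mixed into an
  ROI pair with strength ``s`` (variance preserving), which yields a
  magnitude-squared coherence of about ``s**2`` in that band;
* directed couplings — a lagged copy of a source ROI added to a target
  ROI, which creates Granger causality from source to target.

Baseline segments always use the neutral condition's parameters.  Trial-
to-trial physiological variability is emulated by log-normal jitter on
band amplitudes and small Gaussian jitter on coupling strengths.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .preprocess import BandDefinition, DEFAULT_BANDS, design_fir, _zero_phase_apply

__all__ = [
    "StudyDesign",
    "SyntheticSpec",
    "CoherenceCoupling",
    "DirectedCoupling",
    "TrialRecording",
    "PlantedTruth",
    "generate_trial",
    "generate_cohort",
    "planted_truth",
    "default_spec",
    "null_spec",
]

DEFAULT_CONDITIONS = ("distressed", "excited", "depressed", "relaxed", "neutral")


@dataclass(frozen=True)
class StudyDesign:
    """Cohort layout: who plays, how often, and at what sampling rate."""

    n_participants: int = 10
    n_sessions: int = 4
    trials_per_session: int = 50
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    sampling_rate: float = 500.0
    segment_duration: float = 30.0
    n_rois: int = 10

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_sessions", "trials_per_session", "n_rois"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        n = self.sampling_rate * self.segment_duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sampling_rate x segment_duration must be an integer sample count")
        if len(set(self.conditions)) != len(self.conditions) or not self.conditions:
            raise ValueError("conditions must be a non-empty list of unique labels")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.segment_duration))

    @property
    def n_trials(self) -> int:
        return self.n_participants * self.n_sessions * self.trials_per_session


@dataclass(frozen=True)
class CoherenceCoupling:
    """Shared band-limited source between an ROI pair (symmetric)."""

    condition: str
    band: str
    pair: tuple[int, int]  # 1-based ROI ids, unordered
    strength: float  # in [0, 1]; MSC in the band ~ strength**2


@dataclass(frozen=True)
class DirectedCoupling:
    """Lagged copy of a source ROI added to a target ROI (directional)."""

    condition: str
    source: int  # 1-based ROI id
    target: int
    lag: int  # samples
    coeff: float


@dataclass(frozen=True)
class SyntheticSpec:
    """Condition-dependent generating parameters.

    ``band_gains[condition][band]`` is a scalar or length-``n_rois``
    amplitude multiplier (ROIs not listed default to 1).  The neutral
    condition's parameters double as the baseline-segment parameters.
    """

    band_gains: dict = field(default_factory=dict)
    coherence: tuple[CoherenceCoupling, ...] = ()
    directed: tuple[DirectedCoupling, ...] = ()
    noise_sd: float = 0.2
    power_jitter_sd: float = 0.3
    coupling_jitter_sd: float = 0.05
    directed_jitter_sd: float = 0.02
    baseline_condition: str = "neutral"

    def validate(self, design: StudyDesign) -> None:
        for c in self.coherence:
            if not 0.0 <= c.strength <= 1.0:
                raise ValueError(f"coherence strength {c.strength} outside [0, 1]")
            if not all(1 <= r <= design.n_rois for r in c.pair) or c.pair[0] == c.pair[1]:
                raise ValueError(f"invalid ROI pair {c.pair}")
        for d in self.directed:
            if d.lag < 1:
                raise ValueError("directed coupling lag must be >= 1 sample")
            if not all(1 <= r <= design.n_rois for r in (d.source, d.target)):
                raise ValueError(f"invalid ROI ids in directed coupling {d}")
        self._check_stability(design)

    def _check_stability(self, design: StudyDesign) -> None:
        """Spectral radius of the companion matrix implied by the directed
        couplings must stay below 1 for every condition."""
        for cond in design.conditions:
            edges = [d for d in self.directed if d.condition == cond]
            if not edges:
                continue
            maxlag = max(d.lag for d in edges)
            k = design.n_rois
            A = np.zeros((maxlag, k, k))
            for d in edges:
                A[d.lag - 1, d.target - 1, d.source - 1] += d.coeff
            comp = np.zeros((maxlag * k, maxlag * k))
            comp[:k] = np.concatenate(A, axis=1)
            if maxlag > 1:
                comp[k:, : (maxlag - 1) * k] = np.eye((maxlag - 1) * k)
            rho = np.max(np.abs(np.linalg.eigvals(comp)))
            if rho >= 1.0:
                raise ValueError(
                    f"unstable directed couplings for condition {cond!r} "
                    f"(companion spectral radius {rho:.3f} >= 1)"
                )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)


@dataclass
class TrialRecording:
    """One trial: aligned baseline and emotional ROI-level signals."""

    participant: int
    session: int
    trial_index: int
    condition: str
    baseline_signal: np.ndarray  # (n_rois, n_samples)
    emotional_signal: np.ndarray
    sampling_rate: float

    def validate(self, design: StudyDesign) -> None:
        shape = (design.n_rois, design.n_samples)
        for name in ("baseline_signal", "emotional_signal"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != {shape}")
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains non-finite values")


class _BandFilters:
    """Cached sub-band FIR designs shared by generation and analysis."""

    def __init__(self, bands: tuple[BandDefinition, ...], rate: float):
        transition = min(2.0, min(b.low for b in bands))
        self.bands = bands
        self.taps = {b.name: design_fir(b.low, b.high, rate, transition) for b in bands}
        # Ideal-filter variance of unit white noise confined to the band;
        # used to normalize band components to unit variance.
        self.norm = {b.name: np.sqrt((b.high - b.low) / (rate / 2.0)) for b in bands}


def _condition_gains(spec: SyntheticSpec, condition: str, band: str, n_rois: int) -> np.ndarray:
    gains = np.ones(n_rois)
    table = spec.band_gains.get(condition, {})
    if band in table:
        gains = gains * np.asarray(table[band], dtype=float)
    if gains.shape != (n_rois,):
        raise ValueError(f"band_gains[{condition}][{band}] must broadcast to {n_rois} ROIs")
    return gains


def _synthesize_segment(
    spec: SyntheticSpec,
    design: StudyDesign,
    condition: str,
    rng: np.random.Generator,
    filters: _BandFilters,
) -> np.ndarray:
    """One 30 s multi-ROI segment under a condition's parameters."""
    if condition not in design.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    n = design.n_samples
    pad = int(2 * design.sampling_rate)  # margin absorbing filter transients
    n_gen = n + 2 * pad
    k = design.n_rois

    total = np.zeros((k, n_gen))
    for band in filters.bands:
        noise = rng.standard_normal((k, n_gen))
        comp = _zero_phase_apply(noise, filters.taps[band.name]) / filters.norm[band.name]
        # Shared latent sources create coherence; mixing is variance
        # preserving so band power stays decoupled from coupling strength.
        for c in spec.coherence:
            if c.condition != condition or c.band != band.name:
                continue
            source = rng.standard_normal(n_gen)
            s = c.strength + (rng.normal(0.0, spec.coupling_jitter_sd) if spec.coupling_jitter_sd else 0.0)
            s = float(np.clip(s, 0.0, 1.0))
            shared = _zero_phase_apply(source[None, :], filters.taps[band.name])[0] / filters.norm[band.name]
            for roi in c.pair:
                i = roi - 1
                comp[i] = np.sqrt(1.0 - s) * comp[i] + np.sqrt(s) * shared
        gains = _condition_gains(spec, condition, band.name, k)
        if spec.power_jitter_sd:
            gains = gains * np.exp(rng.normal(0.0, spec.power_jitter_sd, size=k))
        total += gains[:, None] * comp

    # Directed couplings: lagged copies of the pre-coupling source signals
    # (feed-forward, hence unconditionally stable).  The target is mixed as
    # sqrt(1 - c^2) * own + c * lagged source, which roughly preserves its
    # variance so directionality does not confound the power features.
    base = total.copy()
    for d in spec.directed:
        if d.condition != condition:
            continue
        coeff = d.coeff + (rng.normal(0.0, spec.directed_jitter_sd) if spec.directed_jitter_sd else 0.0)
        coeff = float(np.clip(coeff, 0.0, 0.99))
        tgt = d.target - 1
        total[tgt] *= np.sqrt(1.0 - coeff**2)
        total[tgt, d.lag :] += coeff * base[d.source - 1, : -d.lag]

    if spec.noise_sd:
        total += rng.normal(0.0, spec.noise_sd, size=(k, n_gen))
    return total[:, pad : pad + n]


def generate_trial(
    spec: SyntheticSpec,
    design: StudyDesign,
    participant: int,
    condition: str,
    seed,
    session: int = 1,
    trial_index: int = 0,
    _filters: _BandFilters | None = None,
) -> TrialRecording:
    """Synthesize one trial (baseline + emotional segment), reproducibly.

    ``seed`` may be an integer or a :class:`numpy.random.SeedSequence`.
    The baseline segment is drawn first with the baseline (neutral)
    parameters, then the emotional segment with the condition's.
    """
    spec.validate(design)
    if condition not in design.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    filters = _filters or _BandFilters(DEFAULT_BANDS, design.sampling_rate)
    rng = np.random.default_rng(seed)
    baseline = _synthesize_segment(spec, design, spec.baseline_condition, rng, filters)
    emotional = _synthesize_segment(spec, design, condition, rng, filters)
    rec = TrialRecording(
        participant=participant,
        session=session,
        trial_index=trial_index,
        condition=condition,
        baseline_signal=baseline.astype(np.float32),
        emotional_signal=emotional.astype(np.float32),
        sampling_rate=design.sampling_rate,
    )
    rec.validate(design)
    return rec


def cohort_schedule(design: StudyDesign, seed: int) -> pd.DataFrame:
    """Blocked, per-session randomized condition schedule.

    Each session presents every condition ``trials_per_session /
    n_conditions`` times in a seeded shuffled order; non-divisible counts
    fall back (with a warning) to a near-balanced assignment.
    """
    k = len(design.conditions)
    q, r = divmod(design.trials_per_session, k)
    if r:
        warnings.warn(
            f"trials_per_session={design.trials_per_session} not divisible by "
            f"{k} conditions; using near-balanced assignment",
            stacklevel=2,
        )
    rows = []
    counter = 0
    for p in range(1, design.n_participants + 1):
        for s in range(1, design.n_sessions + 1):
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0, p, s)))
            block = list(design.conditions) * q
            block += list(rng.choice(design.conditions, size=r, replace=False))
            order = rng.permutation(len(block))
            for t, j in enumerate(order, start=1):
                rows.append(
                    {
                        "participant": p,
                        "session": s,
                        "trial": t,
                        "condition": block[j],
                        "trial_seed_key": counter,
                    }
                )
                counter += 1
    return pd.DataFrame(rows)


def generate_cohort(
    design: StudyDesign,
    spec: SyntheticSpec,
    seed: int,
    metadata_only: bool = False,
):
    """Synthesize the full cohort (or just its schedule).

    Returns a list of :class:`TrialRecording`, or the schedule
    :class:`~pandas.DataFrame` when ``metadata_only`` is true.  One global
    seed expands into per-trial seeds through a counter-based
    ``SeedSequence`` scheme, so each trial is individually reproducible.
    """
    spec.validate(design)
    schedule = cohort_schedule(design, seed)
    if metadata_only:
        return schedule
    filters = _BandFilters(DEFAULT_BANDS, design.sampling_rate)
    trials = []
    for row in schedule.itertuples():
        trial_seed = np.random.SeedSequence(seed, spawn_key=(1, int(row.trial_seed_key)))
        trials.append(
            generate_trial(
                spec,
                design,
                participant=int(row.participant),
                condition=row.condition,
                seed=trial_seed,
                session=int(row.session),
                trial_index=int(row.trial),
                _filters=filters,
            )
        )
    return trials


@dataclass
class PlantedTruth:
    """Ground-truth record of every planted condition contrast."""

    entries: list[dict]

    def feature_names(self, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS) -> set[str]:
        """Column names (as produced by the feature extractors) that carry
        a planted contrast.  A directed coupling maps to its ordered-pair
        column in every band."""
        names: set[str] = set()
        for e in self.entries:
            if e["family"] == "power":
                names.add(f"pow.{e['band']}.r{e['roi']}.abs")
                names.add(f"pow.{e['band']}.r{e['roi']}.rel")
            elif e["family"] == "msc":
                i, j = sorted(e["pair"])
                names.add(f"msc.{e['band']}.r{i}_r{j}")
            elif e["family"] == "gc":
                i, j = e["pair"]
                for b in bands:
                    names.add(f"gc.{b.name}.r{i}_to_r{j}")
        return names


def planted_truth(spec: SyntheticSpec, design: StudyDesign | None = None) -> PlantedTruth:
    """List every (band, ROI/pair) whose parameters differ from neutral."""
    design = design or StudyDesign()
    neutral = spec.baseline_condition
    entries: list[dict] = []

    band_names = [b.name for b in DEFAULT_BANDS]
    for band in band_names:
        ref = _condition_gains(spec, neutral, band, design.n_rois)
        for cond in design.conditions:
            if cond == neutral:
                continue
            g = _condition_gains(spec, cond, band, design.n_rois)
            for roi in np.nonzero(~np.isclose(g, ref))[0] + 1:
                e = {"family": "power", "band": band, "roi": int(roi)}
                if e not in entries:
                    entries.append(e)

    def coh_strength(cond, band, pair):
        return sum(
            c.strength
            for c in spec.coherence
            if c.condition == cond and c.band == band and tuple(sorted(c.pair)) == pair
        )

    pairs = {(tuple(sorted(c.pair)), c.band) for c in spec.coherence}
    for pair, band in sorted(pairs):
        ref = coh_strength(neutral, band, pair)
        if any(
            not np.isclose(coh_strength(cond, band, pair), ref)
            for cond in design.conditions
            if cond != neutral
        ):
            entries.append({"family": "msc", "band": band, "pair": pair})

    def dir_coeff(cond, edge):
        return sum(
            d.coeff for d in spec.directed if d.condition == cond and (d.source, d.target) == edge
        )

    edges = {(d.source, d.target) for d in spec.directed}
    for edge in sorted(edges):
        ref = dir_coeff(neutral, edge)
        if any(
            not np.isclose(dir_coeff(cond, edge), ref)
            for cond in design.conditions
            if cond != neutral
        ):
            entries.append({"family": "gc", "pair": edge})

    return PlantedTruth(entries=entries)


def null_spec() -> SyntheticSpec:
    """No condition effects at all: every feature family is at its null."""
    return SyntheticSpec(power_jitter_sd=0.0, coupling_jitter_sd=0.0, directed_jitter_sd=0.0)


def default_spec() -> SyntheticSpec:
    """The shipped planted-effects preset.

    Designed so the three feature families carry contrasts of deliberately
    different strength, mirroring what connectivity-versus-power studies
    report: strong condition-dependent coherence (MSC most informative),
    moderate directed-coupling contrasts (Granger intermediate), and weak
    band-power contrasts swamped by realistic trial-to-trial log-normal
    power variability (power least informative).
    """
    po = [7, 8]  # parieto-occipital
    fr = [3, 4]  # frontal

    def gains(rois, value):
        g = np.ones(10)
        g[[r - 1 for r in rois]] = value
        return g.tolist()

    fc = [9]  # fronto-central
    # A theta "engagement" boost shared (with small per-condition spread) by
    # every emotional condition provides the baseline contrast the
    # normalized regime tests for; the alpha/beta gain spreads between
    # conditions are kept small relative to the trial-to-trial power jitter.
    band_gains = {
        "distressed": {"alpha": gains(po, 0.95), "beta": gains(fr, 1.08), "theta": gains(fc, 1.30)},
        "excited": {"alpha": gains(po, 0.92), "beta": gains(fr, 1.05), "theta": gains(fc, 1.35)},
        "depressed": {"alpha": gains(po, 1.05), "beta": gains(fr, 0.95), "theta": gains(fc, 1.25)},
        "relaxed": {"alpha": gains(po, 1.08), "beta": gains(fr, 0.92), "theta": gains(fc, 1.20)},
    }

    coherence = []
    coh_table = {
        ("alpha", (1, 2)): {"neutral": 0.15, "distressed": 0.75, "excited": 0.60, "depressed": 0.45, "relaxed": 0.30},
        ("beta", (5, 6)): {"neutral": 0.15, "distressed": 0.30, "excited": 0.45, "depressed": 0.60, "relaxed": 0.75},
        ("theta", (3, 7)): {"neutral": 0.10, "distressed": 0.50, "excited": 0.25, "depressed": 0.70, "relaxed": 0.40},
        ("gamma", (9, 10)): {"neutral": 0.20, "distressed": 0.35, "excited": 0.65, "depressed": 0.25, "relaxed": 0.50},
    }
    for (band, pair), per_cond in coh_table.items():
        for cond, s in per_cond.items():
            coherence.append(CoherenceCoupling(cond, band, pair, s))

    directed = []
    # Every emotional condition drives every planted edge (baseline has
    # none), with permuted coefficient patterns coding the condition.
    dir_table = {
        (3, 4, 2): {"distressed": 0.85, "excited": 0.60, "depressed": 0.40, "relaxed": 0.50},
        (7, 9, 3): {"distressed": 0.40, "excited": 0.50, "depressed": 0.70, "relaxed": 0.90},
        (2, 6, 1): {"distressed": 0.55, "excited": 0.75, "depressed": 0.45, "relaxed": 0.35},
    }
    for (src, tgt, lag), per_cond in dir_table.items():
        for cond, c in per_cond.items():
            directed.append(DirectedCoupling(cond, src, tgt, lag, c))

    return SyntheticSpec(
        band_gains=band_gains,
        coherence=tuple(coherence),
        directed=tuple(directed),
    )
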