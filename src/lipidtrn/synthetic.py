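"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates a nitrogen-starvation FPKM time course spanning 0-48 h
with dense sampling in the first hour. Planted waves follow baseline-anchored
logistic dynamics on the log2-ratio scale:

    monotonic  r(t) = A * (sigma(t) - sigma(0)) / (1 - sigma(0)),
               sigma(t) = 1 / (1 + exp(-(t - t0)/s))
    transient  a difference of two logistics (a pulse) rescaled to peak A and
               returning within |r| < 1 by the final timepoint

The anchoring forces r(0) = 0 exactly (the reference-sample ratio is zero by
definition) while keeping the plateau/peak at exactly A. Regulator (TR)
profiles are the driven wave's noiseless curve advanced by the planted lag,
negated for repression, and anchored the same way. FPKM values are
reconstructed multiplicatively, x_t = (x0 + 1) * 2**(r + eps) - 1 clipped at
zero with eps ~ Normal(0, sigma), so the noise lives on the log-ratio scale
the filter thresholds operate on. Decoy transcripts are flat noise.

Toy metabolic models (chain / branch / isozyme) come with hand-solved
knockdown outcomes so every rho pathway can be checked against closed-form
LP solutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .expression import ExpressionMatrix, LogRatioMatrix
from .metabolic import MetabolicModel, Reaction

__all__ = [
    "DEFAULT_TIME_GRID",
    "TRN_TIME_GRID",
    "TRN_BENCH_LAG_STEP",
    "WavePlant",
    "TRPlant",
    "SimulationSpec",
    "GroundTruth",
    "simulate_expression",
    "simulate_filter_bench",
    "simulate_toy_metabolic_model",
    "random_toy_network",
    "default_trn_spec",
    "wave_bench_spec",
]

# 0-48 h, 2-min steps up to 12 min so early (minute-scale) responses resolve
DEFAULT_TIME_GRID = (
    0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 18.0, 24.0, 30.0, 45.0, 60.0,
    120.0, 240.0, 480.0, 720.0, 1440.0, 2880.0,
)

# regulator-recovery grid: dense first 12 min, then uniform 15-min sampling; lag
# identification is only meaningful at (or above) the sampling resolution, and
# the planted lags {15, 30, 60, 90} are multiples of it
TRN_TIME_GRID = tuple([0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0] + [float(t) for t in range(15, 2881, 15)])

# lag-scan resolution used by the recovery benchmark (matches TRN_TIME_GRID sampling)
TRN_BENCH_LAG_STEP = 15.0


class SpecError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Planted curves
# ---------------------------------------------------------------------------


def _sigma(t, t0, s):
    return 1.0 / (1.0 + np.exp(-(np.asarray(t, dtype=float) - t0) / s))


def _anchored_monotonic(t, A, t0, s):
    s0 = _sigma(0.0, t0, s)
    return A * (_sigma(t, t0, s) - s0) / (1.0 - s0)


def _anchored_pulse(t, A, t0, s, width):
    raw = _sigma(t, t0, s) - _sigma(t, t0 + width, s)
    raw0 = _sigma(0.0, t0, s) - _sigma(0.0, t0 + width, s)
    peak_t = t0 + width / 2.0
    peak = (_sigma(peak_t, t0, s) - _sigma(peak_t, t0 + width, s)) - raw0
    return A * (raw - raw0) / peak


def _first_crossing(curve, threshold: float, tmax: float) -> float:
    """First t in (0, tmax] with curve(t) >= threshold (curve rises from ~0)."""
    grid = np.linspace(0.0, tmax, 4 * int(tmax) + 1)
    vals = curve(grid)
    above = np.flatnonzero(vals >= threshold)
    if not above.size:
        raise SpecError("planted curve never reaches the crossing threshold")
    i = above[0]
    if i == 0:
        return float(grid[0])
    return float(brentq(lambda t: curve(t) - threshold, grid[i - 1], grid[i]))


@dataclass(frozen=True)
class WavePlant:
    """One planted wave: a dynamics class with a target twofold-crossing time."""

    kind: str  # 'monotonic' | 'transient'
    direction: str  # 'up' | 'down'
    crossing_min: float  # where |r| first exceeds 1.0 (log2 units)
    amplitude: float = 2.0  # plateau / peak height, log2 units
    n_modules: int = 1
    transcripts_per_module: int = 8
    steepness: float | None = None  # logistic time constant s, minutes
    width: float | None = None  # pulse width for transient plants, minutes

    def __post_init__(self) -> None:
        if self.kind not in ("monotonic", "transient"):
            raise SpecError(f"unknown dynamics kind {self.kind!r}")
        if self.direction not in ("up", "down"):
            raise SpecError(f"unknown direction {self.direction!r}")
        if self.amplitude <= 1.0:
            raise SpecError("planted amplitude must exceed the 1.0 log2 fold threshold")
        if self.crossing_min <= 0:
            raise SpecError("crossing time must be positive")

    @property
    def s(self) -> float:
        # transitions unfold over tens of minutes (minute-scale timestamps are
        # meaningful); the cap keeps late waves identifiable under lag scanning
        if self.steepness is not None:
            return self.steepness
        return float(np.clip(0.08 * self.crossing_min, 3.0, 30.0))

    @property
    def w(self) -> float:
        return self.width if self.width is not None else max(120.0, min(0.8 * self.crossing_min, 600.0))

    def curve(self):
        """Signed analytic log2-ratio curve with r(0) = 0 and the requested crossing."""
        A, s, tc = self.amplitude, self.s, self.crossing_min
        if self.kind == "monotonic":
            def shape(t, t0):
                return _anchored_monotonic(t, A, t0, s)
        else:
            w = self.w
            def shape(t, t0):
                return _anchored_pulse(t, A, t0, s, w)

        w_extra = self.w if self.kind == "transient" else 0.0

        def crossing_of(t0):
            tmax = max(t0, tc) + 20 * s + w_extra
            return _first_crossing(lambda t: shape(t, t0), 1.0, tmax)

        # crossing_of is increasing in t0; all planted crossings imply t0 > 0
        t0 = brentq(lambda t0: crossing_of(t0) - tc, 1e-3, tc + 20 * s, xtol=1e-6)
        sign = 1.0 if self.direction == "up" else -1.0
        return lambda t, _t0=t0, _sign=sign: _sign * shape(t, _t0)


@dataclass(frozen=True)
class TRPlant:
    """A regulator driving every module of one planted wave at a fixed lag."""

    wave: int  # index into SimulationSpec.waves
    lag: float  # minutes, TR leads its targets
    sign: str  # 'activation' | 'repression'

    def __post_init__(self) -> None:
        if self.sign not in ("activation", "repression"):
            raise SpecError(f"unknown sign {self.sign!r}")
        if self.lag <= 0:
            raise SpecError("lag must be positive")


@dataclass(frozen=True)
class SimulationSpec:
    waves: tuple[WavePlant, ...]
    tr_plants: tuple[TRPlant, ...] = ()
    decoy_trs: tuple[WavePlant, ...] = ()  # regulator profiles that drive nothing
    times: tuple[float, ...] = DEFAULT_TIME_GRID
    n_null_transcripts: int = 500
    noise_sigma: float = 0.1
    baseline_log_mean: float = 3.0  # ln FPKM; median baseline ~ 20 FPKM
    baseline_log_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise SpecError("times must start at 0 and increase strictly")
        if self.noise_sigma < 0:
            raise SpecError("noise sigma must be >= 0")
        span = t[-1]
        for w in self.waves + self.decoy_trs:
            if w.crossing_min >= span:
                raise SpecError("crossing time outside the sampled span")
        for p in self.tr_plants:
            if not (0 <= p.wave < len(self.waves)):
                raise SpecError("TR plant refers to a wave that does not exist")


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery scoring."""

    kept_rule: dict[str, str]  # transcript -> '1' | '2' | 'both' | 'none'
    module_kind: dict[str, tuple[str, str]]  # module -> (kind, direction)
    module_crossing: dict[str, float]  # module -> analytic twofold-crossing, minutes
    edges: list[tuple[str, str, float, str]]  # (tr, module, lag, sign)
    tr_ids: list[str]
    driver_tr_ids: list[str]
    noiseless_ratios: pd.DataFrame = field(repr=False, default=None)

    @property
    def kept(self) -> set[str]:
        return {t for t, r in self.kept_rule.items() if r != "none"}


def _eval_rules(row: np.ndarray, times: np.ndarray) -> str:
    """Independent (plain-loop) evaluation of the two retention rules."""
    lipid = [480.0, 720.0, 1440.0, 2880.0]
    idx = [int(np.where(times == t)[0][0]) for t in lipid]
    rule1 = all(abs(row[i]) > 1.0 for i in idx)
    rule2 = False
    i = 0
    n = len(row)
    while i < n:
        sgn = 1 if row[i] > 1.0 else (-1 if row[i] < -1.0 else 0)
        if sgn == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and (1 if row[j + 1] > 1.0 else (-1 if row[j + 1] < -1.0 else 0)) == sgn:
            j += 1
        if times[j] - times[i] >= 30.0:
            rule2 = True
            break
        i = j + 1
    return {(False, False): "none", (True, False): "1", (False, True): "2", (True, True): "both"}[
        (rule1, rule2)
    ]


def _baseline_floor(max_amplitude: float) -> float:
    # a transcript planted to drop by `max_amplitude` log2 units (plus noise)
    # must start expressed high enough that the FPKM track never clips at zero
    return 2.0 ** (max_amplitude + 2.0)


def _fpkm_from_ratios(ratios: np.ndarray, baselines: np.ndarray, eps: np.ndarray) -> np.ndarray:
    x = (baselines[:, None] + 1.0) * np.exp2(ratios + eps) - 1.0
    return np.clip(x, 0.0, None)


def simulate_expression(spec: SimulationSpec):
    """Generate (ExpressionMatrix, module assignment, TR id list, GroundTruth)."""
    times = np.asarray(spec.times, dtype=float)
    rng = np.random.default_rng(spec.seed)

    ids: list[str] = []
    rows: list[np.ndarray] = []
    assignment: dict[str, list[str]] = {}
    module_kind: dict[str, tuple[str, str]] = {}
    module_crossing: dict[str, float] = {}
    wave_modules: list[list[str]] = []

    m = 0
    for plant in spec.waves:
        curve = plant.curve()
        members_of_wave = []
        for _ in range(plant.n_modules):
            m += 1
            mid = f"M{m:02d}"
            members_of_wave.append(mid)
            module_kind[mid] = (plant.kind, plant.direction)
            module_crossing[mid] = plant.crossing_min
            assignment[mid] = []
            for k in range(plant.transcripts_per_module):
                tid = f"{mid}_T{k + 1:02d}"
                assignment[mid].append(tid)
                ids.append(tid)
                rows.append(curve(times))
        wave_modules.append(members_of_wave)

    tr_ids: list[str] = []
    driver_ids: list[str] = []
    edges: list[tuple[str, str, float, str]] = []
    for i, plant in enumerate(spec.tr_plants):
        tr_id = f"TR{i + 1:02d}"
        tr_ids.append(tr_id)
        driver_ids.append(tr_id)
        wave = spec.waves[plant.wave]
        curve = wave.curve()
        sgn = 1.0 if plant.sign == "activation" else -1.0
        offset = curve(np.array([plant.lag]))[0]
        ids.append(tr_id)
        rows.append(sgn * (curve(times + plant.lag) - offset))  # anchored: r(0) = 0
        for mid in wave_modules[plant.wave]:
            edges.append((tr_id, mid, plant.lag, plant.sign))
    for j, plant in enumerate(spec.decoy_trs):
        tr_id = f"TR{len(spec.tr_plants) + j + 1:02d}"
        tr_ids.append(tr_id)
        ids.append(tr_id)
        rows.append(plant.curve()(times))

    for k in range(spec.n_null_transcripts):
        ids.append(f"NULL{k + 1:04d}")
        rows.append(np.zeros_like(times))

    ratios = np.asarray(rows)
    kept_rule = {tid: _eval_rules(row, times) for tid, row in zip(ids, ratios)}

    max_amp = max((w.amplitude for w in spec.waves + spec.decoy_trs), default=1.0)
    baselines = np.maximum(
        rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sigma, size=len(ids)),
        _baseline_floor(max_amp),
    )
    eps = (
        rng.normal(0.0, spec.noise_sigma, size=ratios.shape)
        if spec.noise_sigma > 0
        else np.zeros_like(ratios)
    )
    fpkm = _fpkm_from_ratios(ratios, baselines, eps)
    expr = ExpressionMatrix(pd.DataFrame(fpkm, index=ids, columns=times))
    truth = GroundTruth(
        kept_rule=kept_rule,
        module_kind=module_kind,
        module_crossing=module_crossing,
        edges=sorted(edges),
        tr_ids=tr_ids,
        driver_tr_ids=driver_ids,
        noiseless_ratios=pd.DataFrame(ratios, index=ids, columns=times),
    )
    return expr, {k: list(v) for k, v in assignment.items()}, tr_ids, truth


# ---------------------------------------------------------------------------
# Canonical study-condition specs
# ---------------------------------------------------------------------------


def default_trn_spec(seed: int, *, noise_sigma: float = 0.1, n_null_transcripts: int = 500) -> SimulationSpec:
    """Regulator-recovery conditions: 20 TRs, 60 modules in 10 waves, 10 influences.

    Wave crossings are spaced >= 300 min within a dynamics shape so that no
    decoy pairing can be reconciled inside the 15-90 min lag window, and all
    crossings sit at >= 250 min so that a TR curve advanced by up to 90 min is
    still ~0 at t = 0 (the planted lag stays exact after anchoring). Sampling
    uses TRN_TIME_GRID (uniform 15-min after the dense first 12 min): planted
    lags are multiples of the sampling interval, so a regulator's sample track
    is an on-grid shift of its targets'.
    """
    waves = (
        WavePlant("monotonic", "up", 250.0, n_modules=6),
        WavePlant("transient", "up", 400.0, n_modules=6),
        WavePlant("monotonic", "down", 560.0, n_modules=6),
        WavePlant("transient", "down", 700.0, n_modules=6),
        WavePlant("monotonic", "up", 900.0, n_modules=6),
        WavePlant("transient", "up", 1100.0, n_modules=6),
        WavePlant("monotonic", "down", 1300.0, n_modules=6),
        WavePlant("transient", "down", 1500.0, n_modules=6),
        WavePlant("monotonic", "up", 1800.0, n_modules=6),
        WavePlant("monotonic", "down", 2100.0, n_modules=6),
    )
    tr_plants = (
        TRPlant(0, 15.0, "activation"),
        TRPlant(1, 30.0, "repression"),
        TRPlant(2, 60.0, "activation"),
        TRPlant(3, 90.0, "repression"),
        TRPlant(4, 30.0, "activation"),
        TRPlant(5, 60.0, "repression"),
        TRPlant(6, 15.0, "activation"),
        TRPlant(7, 90.0, "activation"),
        TRPlant(8, 60.0, "repression"),
        TRPlant(9, 30.0, "activation"),
    )
    decoy_trs = (
        WavePlant("transient", "up", 160.0, width=150.0),
        WavePlant("transient", "up", 1900.0),
        WavePlant("transient", "down", 2050.0),
        WavePlant("transient", "up", 2200.0),
        WavePlant("transient", "down", 2300.0),
        WavePlant("monotonic", "up", 2400.0),
        WavePlant("monotonic", "down", 2450.0),
        WavePlant("monotonic", "up", 2550.0),
        WavePlant("monotonic", "down", 2600.0),
        WavePlant("monotonic", "up", 2700.0),
    )
    return SimulationSpec(
        waves=waves,
        tr_plants=tr_plants,
        decoy_trs=decoy_trs,
        times=TRN_TIME_GRID,
        noise_sigma=noise_sigma,
        n_null_transcripts=n_null_transcripts,
        seed=seed,
    )


def wave_bench_spec(seed: int, *, noise_sigma: float = 0.0) -> SimulationSpec:
    """Wave-recovery conditions: crossings inside the densely sampled first hour,
    where the sampling (<= 15-min spacing) resolves each logistic transition."""
    waves = (
        WavePlant("monotonic", "up", 14.0, n_modules=2),
        WavePlant("monotonic", "up", 45.0, n_modules=2),
        WavePlant("transient", "up", 28.0, width=150.0, n_modules=2),
        WavePlant("monotonic", "down", 35.0, n_modules=2),
        WavePlant("transient", "down", 50.0, width=200.0, n_modules=2),
        WavePlant("transient", "up", 58.0, width=200.0, n_modules=2),
    )
    return SimulationSpec(waves=waves, noise_sigma=noise_sigma, n_null_transcripts=50, seed=seed)


def simulate_filter_bench(
    seed: int,
    *,
    n_rule1: int = 50,
    n_rule2: int = 50,
    n_both: int = 50,
    n_null: int = 2000,
    noise_sigma: float = 0.0,
    times: tuple[float, ...] = DEFAULT_TIME_GRID,
):
    """Transcripts constructed to pass exactly one retention rule, both, or none.

    rule-1-only  |r| = 1.5 at the four lipid timepoints with alternating sign
                 (no same-sign run longer than one timepoint);
    rule-2-only  r = 1.5 on the consecutive 24-60 min samples (span 36 min),
                 zero at the lipid timepoints;
    both         a monotonic logistic of amplitude 2 crossing at 30 min;
    none         flat.
    """
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    lipid = [480.0, 720.0, 1440.0, 2880.0]
    lipid_idx = [int(np.where(t == x)[0][0]) for x in lipid]
    run_idx = [int(np.where(t == x)[0][0]) for x in (24.0, 30.0, 45.0, 60.0)]

    ids, rows, truth = [], [], {}
    for k in range(n_rule1):
        row = np.zeros_like(t)
        for j, i in enumerate(lipid_idx):
            row[i] = 1.5 if j % 2 == 0 else -1.5
        ids.append(f"R1_{k + 1:04d}")
        rows.append(row)
        truth[ids[-1]] = "1"
    for k in range(n_rule2):
        row = np.zeros_like(t)
        row[run_idx] = 1.5
        ids.append(f"R2_{k + 1:04d}")
        rows.append(row)
        truth[ids[-1]] = "2"
    both_curve = WavePlant("monotonic", "up", 30.0).curve()
    for k in range(n_both):
        ids.append(f"RB_{k + 1:04d}")
        rows.append(both_curve(t))
        truth[ids[-1]] = "both"
    for k in range(n_null):
        ids.append(f"N_{k + 1:05d}")
        rows.append(np.zeros_like(t))
        truth[ids[-1]] = "none"

    ratios = np.asarray(rows)
    baselines = np.maximum(rng.lognormal(3.0, 1.0, size=len(ids)), _baseline_floor(2.0))
    eps = rng.normal(0.0, noise_sigma, size=ratios.shape) if noise_sigma > 0 else np.zeros_like(ratios)
    fpkm = _fpkm_from_ratios(ratios, baselines, eps)
    expr = ExpressionMatrix(pd.DataFrame(fpkm, index=ids, columns=t))
    return expr, truth


# ---------------------------------------------------------------------------
# Toy metabolic fixtures with hand-solved knockdown outcomes
# ---------------------------------------------------------------------------


def simulate_toy_metabolic_model(kind: str) -> tuple[MetabolicModel, dict]:
    """Build a hand-solvable fixture network and its expected knockdown outcomes.

    Ground-truth entries are keyed by gene, then by kd_factor; each records the
    analytically derived biomass ratio, TAG ratio, viability (at the default
    10 % rule) and rho where defined.
    """
    inf = math.inf
    if kind == "chain":
        # uptake -> A -> B; biomass and TAG both drain B, so a knockdown of the
        # shared upstream step scales both objectives equally
        model = MetabolicModel(
            id="toy_chain",
            metabolites=["A", "B"],
            reactions=[
                Reaction("SRC_A", {"A": 1.0}, 0.0, 10.0),
                Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, inf, "g1"),
                Reaction("BM_TAG", {"B": -1.0}, 0.0, inf),
                Reaction("EX_TAG", {"B": -1.0}, 0.0, inf),
            ],
            biomass_id="BM_TAG",
            tag_exchange_id="EX_TAG",
        )
        truth = {
            "g1": {
                2.0: {"bm_ratio": 0.5, "tag_ratio": 0.5, "viable": True, "rho": 1.0},
                16.0: {"bm_ratio": 1.0 / 16.0, "tag_ratio": 1.0 / 16.0, "viable": False, "rho": None},
            }
        }
    elif kind == "branch":
        # biomass needs B and C in equal measure, TAG needs only B: capping the
        # C branch starves biomass while leaving TAG export untouched
        model = MetabolicModel(
            id="toy_branch",
            metabolites=["A", "B", "C", "D"],
            reactions=[
                Reaction("SRC_A", {"A": 1.0}, 0.0, 10.0),
                Reaction("R_B", {"A": -1.0, "B": 1.0}, 0.0, inf, "gB"),
                Reaction("R_C", {"A": -1.0, "C": 1.0}, 0.0, inf, "gC"),
                Reaction("R_D", {"A": -1.0, "D": 1.0}, 0.0, inf, "gD"),
                Reaction("DM_D", {"D": -1.0}, 0.0, inf),
                Reaction("BM_TAG", {"B": -1.0, "C": -1.0}, 0.0, inf),
                Reaction("EX_TAG", {"B": -1.0}, 0.0, inf),
            ],
            biomass_id="BM_TAG",
            tag_exchange_id="EX_TAG",
        )
        truth = {
            "gC": {
                2.0: {"bm_ratio": 0.5, "tag_ratio": 1.0, "viable": True, "rho": 2.0},
                16.0: {"bm_ratio": 1.0 / 16.0, "tag_ratio": 1.0, "viable": False, "rho": None},
            },
            "gB": {2.0: {"bm_ratio": 0.5, "tag_ratio": 0.25, "viable": True, "rho": 0.5}},
            "gD": {  # idle branch: WT flux 0, knockdown pins it at 0 with no effect
                2.0: {"bm_ratio": 1.0, "tag_ratio": 1.0, "viable": True, "rho": 1.0},
                16.0: {"bm_ratio": 1.0, "tag_ratio": 1.0, "viable": True, "rho": 1.0},
            },
        }
    elif kind == "isozyme":
        model = MetabolicModel(
            id="toy_isozyme",
            metabolites=["A", "B"],
            reactions=[
                Reaction("SRC_A", {"A": 1.0}, 0.0, 10.0),
                Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, inf, "g1 or g2"),
                Reaction("BM_TAG", {"B": -1.0}, 0.0, inf),
                Reaction("EX_TAG", {"B": -1.0}, 0.0, inf),
            ],
            biomass_id="BM_TAG",
            tag_exchange_id="EX_TAG",
        )
        truth = {
            "g1": {  # under boolean GPR semantics the isozyme rescues the step
                16.0: {"bm_ratio": 1.0, "tag_ratio": 1.0, "viable": True, "rho": 1.0}
            }
        }
    else:
        raise SpecError(f"unknown toy model kind {kind!r}")
    return model, truth


def random_toy_network(rng: np.random.Generator, max_reactions: int = 10) -> MetabolicModel:
    """Random bounded feed-forward network for LP cross-validation.

    A chain of metabolite layers with 1-2 parallel conversion steps per layer
    and integer stoichiometry; the single bounded source makes every flux
    bounded, so the FBA optimum always exists.
    """
    n_layers = int(rng.integers(2, 5))
    mets = [f"m{i}" for i in range(n_layers + 1)]
    reactions = [Reaction("SRC", {mets[0]: 1.0}, 0.0, float(rng.integers(2, 12)))]
    for i in range(n_layers):
        n_par = int(rng.integers(1, 3))
        for p in range(n_par):
            if len(reactions) >= max_reactions - 1:
                break
            a = float(rng.integers(1, 3))
            b = float(rng.integers(1, 3))
            reactions.append(
                Reaction(f"R{i}_{p}", {mets[i]: -a, mets[i + 1]: b}, 0.0, float(rng.integers(3, 20)))
            )
    reactions.append(Reaction("OBJ", {mets[-1]: -1.0}, 0.0, math.inf))
    return MetabolicModel(id="random_toy", metabolites=mets, reactions=reactions)
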