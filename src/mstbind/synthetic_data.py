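"""Seeded synthetic MST titration data.

Emulates the experimental design of the cMyBP-C × myosin interaction
study: a fixed 0.1 μmol/l Alexa647-labeled target, a 16-point two-fold
serial-dilution titrant ladder, a saturable normalized signal governed by
1:1 mass-action binding, additive Gaussian noise on the normalized scale,
and small replicate numbers (n = 3–8).

The preset registry replays every populated cell of the published
affinity table (cMyBP-C fragments × myosin constructs, Kd in μmol/l),
plus two pairs reported outside the table: the myosin head–tail
interaction (labeled S1 titrated with the S2Δ tail, Kd 0.6 μmol/l, n = 8)
and its no-binding negative control (labeled S2Δ titrated with unlabeled
S2Δ).  "cnd" cells (Kd not reliably determinable) map to the explicit
non-binder sentinel; untested cells raise.

What the generator does *not* emulate: raw thermophoresis time traces,
capillary scans, photobleaching, adsorption, or labeling-efficiency
variation.  See docs/methods.md for the implications.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .equilibria import (
    NON_BINDER,
    BindingDomainError,
    CompetitionSystem,
    Kd,
    NonBinder,
    check_concentration,
    complex_concentration,
)
from .mst_signal import SignalModel, signal_from_occupancy

__all__ = [
    "UntestedInteractionError",
    "BindingScenario",
    "TitrationSeries",
    "ReplicateSet",
    "FRAGMENTS",
    "CONSTRUCTS",
    "TABLE_KDS",
    "CND",
    "scenario",
    "scenario_from_table",
    "head_tail_scenario",
    "negative_control_scenario",
    "iter_preset_keys",
    "default_top",
    "make_titration",
    "make_replicates",
    "make_competition_titration",
    "competition_preset",
    "write_titrations_csv",
    "read_titrations_csv",
    "presets_to_json",
    "DEFAULT_LABELED_TOTAL",
    "DEFAULT_NOISE_SD",
    "DEFAULT_N_POINTS",
    "DEFAULT_DILUTION",
    "TOP_KD_MULTIPLE",
    "MAX_TOP",
]

DEFAULT_LABELED_TOTAL = 0.1  # μmol/l: 100 nmol/l labeled species
DEFAULT_NOISE_SD = 0.03  # SD of additive noise on the normalized signal
DEFAULT_N_POINTS = 16  # standard 16-capillary format
DEFAULT_DILUTION = 2.0  # two-fold serial dilution
TOP_KD_MULTIPLE = 50.0  # ladder top = 50 × Kd ...
MAX_TOP = 500.0  # ... clipped to 500 μmol/l (stock-solubility ceiling)
_DEFAULT_N_REPLICATES = 4  # used where the source reports only "n = 3–7"


class UntestedInteractionError(LookupError):
    """The requested fragment × construct cell was never measured ("—")."""


class CND:
    """Marker type for 'Kd cannot be reliably determined' cells."""

    def __repr__(self) -> str:  # pragma: no cover
        return "cnd"


_CND = CND()

#: Affinity-table row labels (cMyBP-C fragments, i.e. the titrants).
FRAGMENTS: tuple[str, ...] = (
    "C0C2",
    "C0C2-3P",
    "C0C1",
    "C2C4",
    "C5C7",
    "C5C7-N755K",
    "C5C7-R820Q",
    "C5C7-R943Q",
    "C0",
    "C1",
    "m-motif",
    "C2",
    "C3",
    "C4",
    "cMyBP-C",
    "ΔC0C2-cMyBP-C",
)

#: Affinity-table column labels (labeled myosin constructs, i.e. the targets).
CONSTRUCTS: tuple[str, ...] = ("Myosin S1", "miniHMM", "Myosin S2Δ", "miniHMM-P")

# Published Kd mean ± SEM (μmol/l) and replicate count n (None where the
# source prints only the pooled range n = 3–7).  Keys absent -> untested.
TABLE_KDS: dict[tuple[str, str], tuple[float, float, int | None] | CND] = {
    ("C0C2", "Myosin S1"): (3.4, 0.3, 4),
    ("C0C2", "miniHMM"): (3.4, 0.1, 3),
    ("C0C2", "Myosin S2Δ"): (6.5, 0.6, None),
    ("C0C2", "miniHMM-P"): (2.7, 0.1, None),
    ("C0C2-3P", "Myosin S1"): (2.2, 0.2, None),
    ("C0C2-3P", "miniHMM"): (9.7, 0.5, 3),
    ("C0C2-3P", "Myosin S2Δ"): _CND,
    ("C0C2-3P", "miniHMM-P"): (5.0, 0.1, None),
    ("C0C1", "Myosin S1"): (3.8, 0.4, None),
    ("C0C1", "miniHMM"): (10.3, 0.5, 3),
    ("C0C1", "Myosin S2Δ"): (199.3, 14.3, None),
    ("C2C4", "Myosin S1"): (0.38, 0.01, None),
    ("C2C4", "miniHMM"): (4.7, 0.3, None),
    ("C2C4", "Myosin S2Δ"): (292.4, 20.1, None),
    ("C5C7", "Myosin S1"): (0.77, 0.1, None),
    ("C5C7", "miniHMM"): (3.2, 0.2, None),
    ("C5C7", "Myosin S2Δ"): (25.8, 0.8, None),
    ("C5C7-N755K", "Myosin S1"): (0.43, 0.04, None),
    ("C5C7-N755K", "Myosin S2Δ"): (73.9, 6.9, None),
    ("C5C7-R820Q", "Myosin S1"): (1.30, 0.04, None),
    ("C5C7-R820Q", "Myosin S2Δ"): (59.1, 2.9, None),
    ("C5C7-R943Q", "Myosin S1"): (0.61, 0.05, None),
    ("C5C7-R943Q", "Myosin S2Δ"): (32.6, 2.5, None),
    ("C0", "Myosin S1"): (91.3, 4.5, None),
    ("C0", "miniHMM"): (335.1, 17.7, None),
    ("C0", "Myosin S2Δ"): _CND,
    ("C1", "Myosin S1"): (3.8, 0.2, 3),
    ("C1", "miniHMM"): (17.0, 0.5, None),
    ("C1", "Myosin S2Δ"): _CND,
    ("m-motif", "Myosin S1"): (183.1, 7.1, None),
    ("m-motif", "miniHMM"): (49.7, 3.8, None),
    ("m-motif", "Myosin S2Δ"): (41.4, 2.3, None),
    ("C2", "Myosin S1"): (42.3, 1.2, None),
    ("C2", "miniHMM"): (501.9, 57.6, None),
    ("C2", "Myosin S2Δ"): _CND,
    ("C3", "Myosin S1"): (25.0, 0.6, None),
    ("C4", "Myosin S1"): (2.5, 0.1, None),
    ("cMyBP-C", "Myosin S1"): (0.30, 0.02, None),
    ("ΔC0C2-cMyBP-C", "Myosin S1"): (0.51, 0.02, None),
}

# Pairs reported outside the fragment × construct table.
_EXTRA_PRESETS: dict[tuple[str, str], tuple[Kd, float | None, int]] = {
    # head-tail interaction: S2Δ titrated into labeled S1, Kd 0.6 ± 0.1, n = 8
    ("Myosin S2Δ", "Myosin S1"): (0.6, 0.1, 8),
    # negative control: unlabeled S2Δ into labeled S2Δ, no binding, n = 8
    ("Myosin S2Δ", "Myosin S2Δ"): (NON_BINDER, None, 8),
}


@dataclass(frozen=True)
class BindingScenario:
    """Ground truth for one labeled-target × titrant pair."""

    target_name: str
    titrant_name: str
    kd_true: Kd
    labeled_total: float = DEFAULT_LABELED_TOTAL
    signal: SignalModel = field(default_factory=SignalModel)
    noise_sd: float = DEFAULT_NOISE_SD
    n_replicates: int = _DEFAULT_N_REPLICATES

    def __post_init__(self) -> None:
        if check_concentration(self.labeled_total, "labeled_total") == 0.0:
            raise BindingDomainError("labeled_total must be > 0")
        if self.noise_sd < 0:
            raise BindingDomainError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise BindingDomainError("n_replicates must be >= 1")
        if self.kd_true is not NON_BINDER:
            check_concentration(float(self.kd_true), "kd_true")

    @property
    def is_binder(self) -> bool:
        return self.kd_true is not NON_BINDER


@dataclass(frozen=True)
class TitrationSeries:
    """One titration experiment: ascending titrant totals with signals."""

    titrant_totals: np.ndarray
    signals: np.ndarray
    labeled_total: float
    seed: int
    scenario: BindingScenario | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "titrant_totals", np.asarray(self.titrant_totals, dtype=float)
        )
        object.__setattr__(self, "signals", np.asarray(self.signals, dtype=float))
        if self.titrant_totals.size < 8:
            raise BindingDomainError("a titration needs >= 8 points")
        if self.titrant_totals.shape != self.signals.shape:
            raise BindingDomainError("concentrations and signals differ in length")
        if np.any(np.diff(self.titrant_totals) <= 0):
            raise BindingDomainError("titrant concentrations must be strictly ascending")
        check_concentration(self.labeled_total, "labeled_total")

    @property
    def top(self) -> float:
        return float(self.titrant_totals[-1])


@dataclass(frozen=True)
class ReplicateSet:
    """n replicate series of one scenario with distinct seeds."""

    series: tuple[TitrationSeries, ...]

    def __post_init__(self) -> None:
        seeds = [s.seed for s in self.series]
        if len(set(seeds)) != len(seeds):
            raise BindingDomainError(f"replicate seeds must be distinct, got {seeds}")
        scenarios = {id(s.scenario) for s in self.series if s.scenario is not None}
        if len({(s.scenario.titrant_name, s.scenario.target_name)
                for s in self.series if s.scenario is not None}) > 1:
            raise BindingDomainError("replicates must share one scenario")

    @property
    def n(self) -> int:
        return len(self.series)


def _build_scenario(
    titrant: str, target: str, entry, **overrides
) -> BindingScenario:
    if isinstance(entry, CND):
        kd: Kd = NON_BINDER
        n = _DEFAULT_N_REPLICATES
    else:
        kd, _sem, n = entry
        n = n or _DEFAULT_N_REPLICATES
    kwargs = dict(
        target_name=target,
        titrant_name=titrant,
        kd_true=kd,
        n_replicates=n,
    )
    kwargs.update(overrides)
    return BindingScenario(**kwargs)


def scenario_from_table(fragment: str, construct: str, **overrides) -> BindingScenario:
    """Scenario for one populated affinity-table cell.

    ``cnd`` cells yield a non-binder scenario; untested cells ("—") raise
    :class:`UntestedInteractionError`; labels outside the table vocabulary
    raise ``KeyError``.
    """
    if fragment not in FRAGMENTS:
        raise KeyError(f"unknown fragment {fragment!r}")
    if construct not in CONSTRUCTS:
        raise KeyError(f"unknown myosin construct {construct!r}")
    entry = TABLE_KDS.get((fragment, construct))
    if entry is None:
        raise UntestedInteractionError(
            f"{fragment} × {construct} was not tested ('—' cell)"
        )
    return _build_scenario(fragment, construct, entry, **overrides)


def scenario(titrant: str, target: str, **overrides) -> BindingScenario:
    """General preset lookup: affinity-table cells plus the head–tail pair
    and the tail self-control."""
    if (titrant, target) in _EXTRA_PRESETS:
        kd, _sem, n = _EXTRA_PRESETS[(titrant, target)]
        kwargs = dict(
            target_name=target, titrant_name=titrant, kd_true=kd, n_replicates=n
        )
        kwargs.update(overrides)
        return BindingScenario(**kwargs)
    return scenario_from_table(titrant, target, **overrides)


def head_tail_scenario(**overrides) -> BindingScenario:
    """Labeled myosin S1 titrated with the S2Δ tail (Kd 0.6 μmol/l, n = 8)."""
    return scenario("Myosin S2Δ", "Myosin S1", **overrides)


def negative_control_scenario(**overrides) -> BindingScenario:
    """Labeled S2Δ titrated with unlabeled S2Δ: the no-binding control."""
    return scenario("Myosin S2Δ", "Myosin S2Δ", **overrides)


def iter_preset_keys() -> Iterable[tuple[str, str]]:
    """All (titrant, target) preset keys: table cells then the extras."""
    yield from TABLE_KDS.keys()
    yield from _EXTRA_PRESETS.keys()


def default_top(scen: BindingScenario) -> float:
    """Default ladder top: 50 × Kd, clipped to 500 μmol/l.

    Guarantees both plateaus for mid-range affinities and honestly fails
    (saturation flag, downstream 'cnd') for the weakest ones.  Non-binders
    get the full 500 μmol/l ceiling.
    """
    if not scen.is_binder:
        return MAX_TOP
    return float(min(TOP_KD_MULTIPLE * float(scen.kd_true), MAX_TOP))


def _ladder(top: float, n_points: int, dilution: float) -> np.ndarray:
    if n_points < 8:
        raise BindingDomainError("n_points must be >= 8")
    if dilution <= 1.0:
        raise BindingDomainError("dilution must be > 1")
    if top <= 0.0:
        raise BindingDomainError("ladder top must be > 0")
    return top / dilution ** np.arange(n_points - 1, -1, -1, dtype=float)


def noiseless_signal(scen: BindingScenario, titrant_totals: np.ndarray) -> np.ndarray:
    """Deterministic forward model: depletion-exact occupancy -> signal."""
    lt = np.asarray(titrant_totals, dtype=float)
    if scen.is_binder:
        rl = complex_concentration(scen.labeled_total, lt, float(scen.kd_true))
        theta = rl / scen.labeled_total
    else:
        theta = np.zeros_like(lt)
    return signal_from_occupancy(theta, scen.signal)


def make_titration(
    scen: BindingScenario,
    n_points: int = DEFAULT_N_POINTS,
    top: float | None = None,
    dilution: float = DEFAULT_DILUTION,
    seed: int = 0,
) -> TitrationSeries:
    """Simulate one titration series.

    Signals are the noiseless mass-action forward model plus i.i.d.
    Gaussian noise of SD ``scenario.noise_sd`` on the normalized scale;
    the series is fully determined by ``seed``.  Binder scenarios whose
    ladder top is below 10 × Kd — i.e. whose bound plateau cannot be
    reached — are flagged ``"saturation unreachable"`` but still produced.
    """
    if top is None:
        top = default_top(scen)
    conc = _ladder(top, n_points, dilution)
    rng = np.random.default_rng(seed)
    y = noiseless_signal(scen, conc)
    if scen.noise_sd > 0:
        y = y + rng.normal(0.0, scen.noise_sd, size=conc.shape)
    flags: tuple[str, ...] = ()
    if scen.is_binder and top < 10.0 * float(scen.kd_true):
        flags = ("saturation unreachable",)
    return TitrationSeries(
        titrant_totals=conc,
        signals=y,
        labeled_total=scen.labeled_total,
        seed=seed,
        scenario=scen,
        flags=flags,
    )


def make_replicates(
    scen: BindingScenario,
    n: int | None = None,
    base_seed: int = 1,
    **titration_kwargs,
) -> ReplicateSet:
    """n replicate titrations with seeds ``base_seed, base_seed+1, ...``."""
    if n is None:
        n = scen.n_replicates
    return ReplicateSet(
        series=tuple(
            make_titration(scen, seed=base_seed + i, **titration_kwargs)
            for i in range(n)
        )
    )


def make_competition_titration(
    sys_template: CompetitionSystem,
    ladder: Sequence[float],
    seed: int = 0,
    signal_free: float = 0.0,
    signal_bound_a: float = 0.35,
    signal_bound_b: float = 1.0,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> TitrationSeries:
    """Simulate titrating ligand B into a fixed receptor + competitor-A mix.

    The receptor, competitor total and both Kds are taken from
    ``sys_template``; its ``titrant_b_total`` is ignored and replaced by
    each ladder point.  The observable is a composite of the two bound
    states with *distinct* amplitudes (MST cannot tell which unlabeled
    partner is bound, but the two complexes need not perturb thermophoresis
    identically; with a single shared bound signal a B-titration into a
    pre-saturated receptor would be flat).  Amplitudes are configurable.
    """
    from .equilibria import fraction_bound, solve_competition  # local: avoid cycle noise

    conc = np.asarray(ladder, dtype=float)
    if np.any(np.diff(conc) <= 0):
        raise BindingDomainError("ladder must be strictly ascending")
    theta_a = np.empty_like(conc)
    theta_b = np.empty_like(conc)
    for i, bt in enumerate(conc):
        state = solve_competition(
            CompetitionSystem(
                receptor_total=sys_template.receptor_total,
                competitor_a_total=sys_template.competitor_a_total,
                titrant_b_total=float(bt),
                kd_a=sys_template.kd_a,
                kd_b=sys_template.kd_b,
            )
        )
        rt = sys_template.receptor_total
        theta_a[i] = state.complexes[("R", "A")] / rt if rt else 0.0
        theta_b[i] = state.complexes[("R", "B")] / rt if rt else 0.0
    y = (
        signal_free
        + theta_a * (signal_bound_a - signal_free)
        + theta_b * (signal_bound_b - signal_free)
    )
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=conc.shape)
    return TitrationSeries(
        titrant_totals=conc,
        signals=y,
        labeled_total=sys_template.receptor_total,
        seed=seed,
        scenario=None,
        flags=("competition",),
    )


#: Competitor (C2C4) concentration in the competition-experiment preset.
#: Not printed in the source; inferred from the reported EC50 shift
#: 0.8 -> 3.8 μmol/l via the Cheng–Prusoff relation
#: A_t = Kd_a (EC50' / Kd_b − 1) ≈ 1.5 μmol/l.
COMPETITOR_A_TOTAL_INFERRED = 1.5


def competition_preset(
    titrant_b_total: float = 0.0,
    labeled_total: float = DEFAULT_LABELED_TOTAL,
) -> CompetitionSystem:
    """The C5C7-into-(S1 + C2C4) competition experiment as a system template.

    Kd_a (C2C4 × S1) = 0.38 μmol/l, Kd_b (C5C7 × S1) = 0.77 μmol/l,
    competitor total 1.5 μmol/l (inferred — see
    :data:`COMPETITOR_A_TOTAL_INFERRED`).
    """
    return CompetitionSystem(
        receptor_total=labeled_total,
        competitor_a_total=COMPETITOR_A_TOTAL_INFERRED,
        titrant_b_total=titrant_b_total,
        kd_a=0.38,
        kd_b=0.77,
    )


# ---------------------------------------------------------------------------
# I/O: instrument-export-like CSV and preset JSON
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "series_id",
    "replicate",
    "titrant_umol_l",
    "signal",
    "labeled_total_umol_l",
    "seed",
]


def _series_id(s: TitrationSeries) -> str:
    if s.scenario is not None:
        return f"{s.scenario.titrant_name}|{s.scenario.target_name}"
    return "series"


def write_titrations_csv(path, series: Iterable[TitrationSeries] | ReplicateSet) -> None:
    """Write titration series as a flat CSV (UTF-8, '.' decimal).

    Columns: series_id, replicate, titrant_umol_l, signal,
    labeled_total_umol_l, seed.  ``series_id`` is ``"titrant|target"`` for
    preset-derived series.
    """
    if isinstance(series, ReplicateSet):
        series = series.series
    rows = []
    for rep, s in enumerate(series):
        sid = _series_id(s)
        for lt, y in zip(s.titrant_totals, s.signals):
            rows.append((sid, rep, lt, y, s.labeled_total, s.seed))
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False, encoding="utf-8")


def read_titrations_csv(path) -> list[TitrationSeries]:
    """Read series back from the CSV dialect of :func:`write_titrations_csv`.

    Scenario references are not reconstructed (the file carries data, not
    ground truth); ``series_id`` round-trips through the returned flags as
    ``("id:<series_id>",)``.
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise BindingDomainError(f"titration CSV missing columns: {sorted(missing)}")
    out = []
    for (sid, rep), grp in df.groupby(["series_id", "replicate"], sort=True):
        grp = grp.sort_values("titrant_umol_l")
        out.append(
            TitrationSeries(
                titrant_totals=grp["titrant_umol_l"].to_numpy(),
                signals=grp["signal"].to_numpy(),
                labeled_total=float(grp["labeled_total_umol_l"].iloc[0]),
                seed=int(grp["seed"].iloc[0]),
                scenario=None,
                flags=(f"id:{sid}",),
            )
        )
    return out


def presets_to_json(path=None) -> str:
    """Serialize the preset registry as JSON keyed by fragment then construct.

    Cells are ``{"kd_umol_l", "sem_umol_l", "n"}`` / ``"cnd"`` /
    ``"untested"``; the two extra (non-table) presets appear under their
    titrant name.  Returns the JSON text; also writes it if ``path`` given.
    """
    tree: dict[str, dict[str, object]] = {}
    for titrant, target in iter_preset_keys():
        entry = TABLE_KDS.get((titrant, target), _EXTRA_PRESETS.get((titrant, target)))
        cell: object
        if isinstance(entry, CND):
            cell = "cnd"
        else:
            kd, sem, n = entry
            cell = {
                "kd_umol_l": None if kd is NON_BINDER else kd,
                "sem_umol_l": sem,
                "n": n,
            }
        tree.setdefault(titrant, {})[target] = cell
    for fragment in FRAGMENTS:
        for construct in CONSTRUCTS:
            tree.setdefault(fragment, {}).setdefault(construct, "untested")
    text = json.dumps(tree, ensure_ascii=False, indent=2)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
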