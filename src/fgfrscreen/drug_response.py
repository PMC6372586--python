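"""Prednisolone dose-response analysis under ligand/inhibitor co-exposure.

Viability signals are normalized to the drug-free control *of the same
condition*, so a condition containing FGF2 and/or the FGFR inhibitor AZD4547
is automatically corrected for the single-agent cytotoxicity of the
modulator(s), and the dose series measures only the glucocorticoid effect.
The IC50 is the concentration at which 50% of cells survive relative to that
control, located by interpolating the survival curve between the bracketing
doses; curves that never cross 50% are censored at the range boundary.

Cross-condition comparisons use IC50 fold changes and an exact Wilcoxon
matched-pairs signed-rank test.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CONDITIONS",
    "PlateData",
    "Censoring",
    "Ic50Result",
    "FoldChange",
    "PairedTestResult",
    "PanelReport",
    "InvalidControlError",
    "DegenerateInputError",
    "ConfigurationError",
    "normalize_viability",
    "single_agent_effect",
    "estimate_ic50",
    "fold_change",
    "wilcoxon_matched_pairs",
    "analyze_panel",
]

CONDITIONS = ("CTRL", "FGF2", "AZD", "FGF2_AZD")


class InvalidControlError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


@dataclass
class PlateData:
    """One cell line × condition dose series with replicate signals.

    ``raw[i]`` holds the replicate signals at ``doses[i]``; ``zero_dose_raw``
    is the drug-free well of this condition (modulators still present);
    ``untreated_raw`` is the no-drug/no-modulator reference, if measured.
    """

    cell_line: str
    condition: str
    doses: np.ndarray
    raw: list[np.ndarray]
    zero_dose_raw: np.ndarray
    untreated_raw: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.raw = [np.asarray(r, dtype=float) for r in self.raw]
        self.zero_dose_raw = np.asarray(self.zero_dose_raw, dtype=float)
        if self.untreated_raw is not None:
            self.untreated_raw = np.asarray(self.untreated_raw, dtype=float)
        if self.doses.size < 2 or np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be >=2 strictly increasing concentrations")
        if len(self.raw) != self.doses.size:
            raise ValueError("one replicate list per dose required")
        if any(r.size < 1 for r in self.raw) or self.zero_dose_raw.size < 1:
            raise ValueError("each dose needs at least one replicate")
        for arr in (*self.raw, self.zero_dose_raw):
            if np.any(arr < 0):
                raise ValueError("viability signals must be non-negative")

    @property
    def n_replicates(self) -> int:
        return min(r.size for r in self.raw)


class Censoring(enum.Enum):
    NONE = "none"
    ABOVE_MAX = "above_max"
    BELOW_MIN = "below_min"


@dataclass(frozen=True)
class Ic50Result:
    cell_line: str
    condition: str
    ic50: float  # nan when censored
    censored: Censoring
    curve: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def label(self) -> str:
        if self.censored is Censoring.NONE:
            return f"{self.ic50:.4g}"
        return (">" if self.censored is Censoring.ABOVE_MAX else "<") + f"{self.ic50:.4g}"


@dataclass(frozen=True)
class FoldChange:
    cell_line: str
    numerator_condition: str
    denominator_condition: str
    fold: float  # nan when undefined
    reason: str = ""  # e.g. CENSORED

    @property
    def defined(self) -> bool:
        return not math.isnan(self.fold)


@dataclass(frozen=True)
class PairedTestResult:
    n_pairs: int
    statistic: float  # signed-rank sum W+ (positive differences)
    p_two_sided: float
    method: str  # EXACT | NORMAL_APPROX


def normalize_viability(plate: PlateData) -> np.ndarray:
    """Per-dose mean survival fraction relative to the condition's own
    drug-free control.  Values above 1 (growth stimulation) are permitted."""
    control = float(np.mean(plate.zero_dose_raw))
    if control <= 0:
        raise InvalidControlError(
            f"{plate.cell_line}/{plate.condition}: non-positive drug-free control mean"
        )
    return np.array([float(np.mean(r)) / control for r in plate.raw])


def single_agent_effect(plate: PlateData) -> Optional[float]:
    """Kill fraction of the condition's modulator(s) alone:
    1 − mean(drug-free control) / mean(untreated).  Negative values indicate
    growth stimulation and are reported as-is; None when no untreated wells
    were measured."""
    if plate.untreated_raw is None or plate.untreated_raw.size == 0:
        return None
    untreated = float(np.mean(plate.untreated_raw))
    if untreated <= 0:
        raise InvalidControlError(f"{plate.cell_line}: non-positive untreated mean")
    return min(1.0, 1.0 - float(np.mean(plate.zero_dose_raw)) / untreated)


def _logit(s: float, eps: float = 1e-9) -> float:
    s = min(max(s, eps), 1.0 - eps)
    return math.log(s / (1.0 - s))


def estimate_ic50(
    doses: Sequence[float],
    survival: Sequence[float],
    cell_line: str = "",
    condition: str = "",
    interp: str = "logit",
) -> Ic50Result:
    """Concentration at which survival crosses 0.5.

    Scans from the lowest dose for the first adjacent pair bracketing 0.5
    (an exact hit at a measured dose returns that dose) and interpolates
    against log10-dose — by default on the logit of survival, which is exact
    for sigmoid (Hill) curves; ``interp='linear'`` interpolates survival
    itself.  Curves entirely above (below) 0.5 are censored ABOVE_MAX
    (BELOW_MIN) at the range boundary.
    """
    d = np.asarray(doses, dtype=float)
    s = np.asarray(survival, dtype=float)
    if d.size < 2 or np.any(np.diff(d) <= 0):
        raise ValueError("doses must be >=2 strictly increasing concentrations")
    if d.size != s.size or not np.all(np.isfinite(s)):
        raise ValueError("survival must be finite and match doses")
    if interp not in ("logit", "linear"):
        raise ValueError(f"unknown interpolation {interp!r}")

    for i in range(d.size):
        if s[i] == 0.5:
            return Ic50Result(cell_line, condition, float(d[i]), Censoring.NONE, s)
        if i + 1 < d.size and (s[i] - 0.5) * (s[i + 1] - 0.5) < 0:
            x0, x1 = math.log10(d[i]), math.log10(d[i + 1])
            if interp == "logit":
                a, b = _logit(float(s[i])), _logit(float(s[i + 1]))
            else:
                a, b = float(s[i]) - 0.5, float(s[i + 1]) - 0.5
            frac = a / (a - b)
            return Ic50Result(
                cell_line, condition, 10 ** (x0 + frac * (x1 - x0)), Censoring.NONE, s
            )
    if np.all(s > 0.5):
        return Ic50Result(cell_line, condition, float(d[-1]), Censoring.ABOVE_MAX, s)
    return Ic50Result(cell_line, condition, float(d[0]), Censoring.BELOW_MIN, s)


def fold_change(a: Ic50Result, b: Ic50Result) -> FoldChange:
    """IC50 ratio a/b for one cell line; undefined when either is censored."""
    if a.cell_line != b.cell_line:
        raise ValueError("fold change requires the same cell line")
    if a.censored is not Censoring.NONE or b.censored is not Censoring.NONE:
        return FoldChange(a.cell_line, a.condition, b.condition, float("nan"), "CENSORED")
    return FoldChange(a.cell_line, a.condition, b.condition, a.ic50 / b.ic50)


# ---------------------------------------------------------------------------
# Exact Wilcoxon matched-pairs signed-rank test


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Counts of assignments by doubled positive-rank sum over all 2^m sign
    vectors (dynamic programme; identical to full enumeration)."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def wilcoxon_matched_pairs(
    x: Sequence[float], y: Sequence[float], max_exact: int = 25
) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped; tied absolute differences receive
    mid-ranks.  For up to ``max_exact`` informative pairs the two-sided p is
    exact — the fraction of all 2^m sign assignments whose rank sum deviates
    from the null centre at least as far as observed; beyond that a normal
    approximation with tie correction and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    diffs = x - y
    diffs = diffs[diffs != 0]
    m = diffs.size
    if m == 0:
        raise DegenerateInputError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    total = float(ranks.sum())  # m(m+1)/2

    if m <= max_exact:
        ranks2 = np.rint(2 * ranks).astype(int)  # mid-ranks doubled -> integers
        counts = _signed_rank_distribution(ranks2)
        centre = int(ranks2.sum()) / 2.0  # null centre on the doubled scale
        dev = abs(2.0 * w_plus - centre)  # observed deviation, doubled scale
        sums = np.arange(counts.size)
        extreme = np.abs(sums - centre) >= dev - 1e-9
        p = float(counts[extreme].sum() / counts.sum())
        return PairedTestResult(m, w_plus, min(p, 1.0), "EXACT")

    mean = total / 2.0
    _, tie_counts = np.unique(np.abs(diffs), return_counts=True)
    var = m * (m + 1) * (2 * m + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    delta = w_plus - mean
    z = (delta - 0.5 * np.sign(delta)) / math.sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return PairedTestResult(m, w_plus, p, "NORMAL_APPROX")


# ---------------------------------------------------------------------------
# Panel-level analysis


@dataclass
class PanelReport:
    """Per-line IC50s/folds/flags plus panel-level summaries."""

    lines: pd.DataFrame
    ic50s: dict[tuple[str, str], Ic50Result]
    n_responsive: int
    mean_fold_responsive: float
    wilcoxon_by_replicate: Optional[PairedTestResult]
    wilcoxon_by_line: Optional[PairedTestResult]
    responsive_threshold: float
    reversal_tolerance: float


def _replicate_ic50(plate: PlateData, r: int, interp: str) -> Ic50Result:
    """IC50 from a single replicate's curve, normalized to the same
    replicate's drug-free well."""
    control = float(plate.zero_dose_raw[min(r, plate.zero_dose_raw.size - 1)])
    if control <= 0:
        raise InvalidControlError(f"{plate.cell_line}/{plate.condition}: bad replicate control")
    survival = np.array([float(raw[r]) / control for raw in plate.raw])
    return estimate_ic50(plate.doses, survival, plate.cell_line, plate.condition, interp)


def analyze_panel(
    plates: Sequence[PlateData],
    responsive_threshold: float = 1.5,
    reversal_tolerance: float = 0.25,
    interp: str = "logit",
) -> PanelReport:
    """Analyze a cell-line panel: per-condition IC50s, the FGF2/CTRL fold
    with a responsiveness flag (fold >= threshold), reversal by the FGFR
    inhibitor (FGF2_AZD/CTRL fold within tolerance of 1), single-agent kill
    fractions, and matched-pairs tests of CTRL vs FGF2 IC50s.

    The Wilcoxon test is reported under both pairings — one pair per
    replicate and one pair per cell line — since either is defensible for
    unevenly replicated panels.
    """
    by_line: dict[str, dict[str, PlateData]] = {}
    for plate in plates:
        if plate.condition not in CONDITIONS:
            raise ConfigurationError(f"unknown condition {plate.condition!r}")
        slot = by_line.setdefault(plate.cell_line, {})
        if plate.condition in slot:
            raise ConfigurationError(
                f"duplicate plate for {plate.cell_line}/{plate.condition}"
            )
        slot[plate.condition] = plate

    ic50s: dict[tuple[str, str], Ic50Result] = {}
    rows = []
    rep_pairs_x: list[float] = []
    rep_pairs_y: list[float] = []
    line_pairs_x: list[float] = []
    line_pairs_y: list[float] = []

    for line in sorted(by_line):
        conds = by_line[line]
        if "CTRL" not in conds:
            raise ConfigurationError(f"cell line {line}: CTRL condition missing")
        for cond, plate in conds.items():
            ic50s[(line, cond)] = estimate_ic50(
                plate.doses, normalize_viability(plate), line, cond, interp
            )
        ctrl = ic50s[(line, "CTRL")]
        fgf2 = ic50s.get((line, "FGF2"))
        combo = ic50s.get((line, "FGF2_AZD"))

        fold = fold_change(fgf2, ctrl) if fgf2 else None
        responsive = bool(fold and fold.defined and fold.fold >= responsive_threshold)
        rev_fold = fold_change(combo, ctrl) if combo else None
        reversed_flag = bool(
            rev_fold and rev_fold.defined and abs(rev_fold.fold - 1.0) <= reversal_tolerance
        )
        kills = {
            cond: single_agent_effect(conds[cond])
            for cond in ("FGF2", "AZD", "FGF2_AZD")
            if cond in conds
        }

        if fgf2 is not None:
            if fold and fold.defined:
                line_pairs_x.append(fgf2.ic50)
                line_pairs_y.append(ctrl.ic50)
            n_rep = min(conds["CTRL"].n_replicates, conds["FGF2"].n_replicates)
            for r in range(n_rep):
                a = _replicate_ic50(conds["FGF2"], r, interp)
                b = _replicate_ic50(conds["CTRL"], r, interp)
                if a.censored is Censoring.NONE and b.censored is Censoring.NONE:
                    rep_pairs_x.append(a.ic50)
                    rep_pairs_y.append(b.ic50)

        rows.append(
            {
                "cell_line": line,
                "ic50_ctrl": ctrl.label,
                "ic50_fgf2": fgf2.label if fgf2 else "",
                "ic50_fgf2_azd": combo.label if combo else "",
                "fgf2_fold": fold.fold if fold else float("nan"),
                "responsive": responsive,
                "reversal_fold": rev_fold.fold if rev_fold else float("nan"),
                "reversed": reversed_flag,
                "fgf2_kill": kills.get("FGF2"),
                "azd_kill": kills.get("AZD"),
                "fgf2_azd_kill": kills.get("FGF2_AZD"),
            }
        )

    lines_df = pd.DataFrame(rows)
    responsive_folds = (
        lines_df.loc[lines_df["responsive"], "fgf2_fold"] if not lines_df.empty else pd.Series(dtype=float)
    )
    mean_fold = float(responsive_folds.mean()) if len(responsive_folds) else float("nan")

    def _maybe_test(x, y):
        try:
            return wilcoxon_matched_pairs(x, y) if len(x) else None
        except DegenerateInputError:
            return None

    return PanelReport(
        lines=lines_df,
        ic50s=ic50s,
        n_responsive=int(lines_df["responsive"].sum()) if not lines_df.empty else 0,
        mean_fold_responsive=mean_fold,
        wilcoxon_by_replicate=_maybe_test(rep_pairs_x, rep_pairs_y),
        wilcoxon_by_line=_maybe_test(line_pairs_x, line_pairs_y),
        responsive_threshold=responsive_threshold,
        reversal_tolerance=reversal_tolerance,
    )
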