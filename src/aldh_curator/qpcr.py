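"""RT-qPCR quantification: Cq calling, efficiency, geNorm, NRQ.

The chain implemented here is the standard efficiency-corrected
relative-quantification workflow:

* **Cq calling** — baseline-subtracted fluorescence crossing a fixed
  threshold (default 75 RFU), with log-linear interpolation between the
  bracketing cycles (fluorescence is exponential in cycle number, so
  interpolation is linear in log-fluorescence).
* **Amplification efficiency** — window-of-linearity regression: for
  each curve, every contiguous window of 3-5 cycles of log10
  baseline-subtracted fluorescence is fit; among windows with
  R^2 >= 0.998 the steepest is taken (the exponential phase), and the
  per-cycle amplification factor is 10^slope.  Efficiency E is
  factor - 1, so a perfect doubling has factor 2 and E 1; both are
  reported to avoid the two clashing conventions in the literature.
* **3':5' integrity ratio** — comparative-Cq ratio factor^(Cq5 - Cq3)
  between amplicons near the two ends of one transcript; ratios below
  1.5 pass the RNA-integrity check.
* **geNorm stability** — for reference j, M_j is the mean over partner
  references k of the standard deviation across samples of
  log2(q_j/q_k), with q = factor^(minCq - Cq); the worst reference is
  removed iteratively and the surviving pair is selected.
* **NRQ** — per target, relative quantity RQ = factor^(Cq_cal - Cq_s)
  against the calibrator sample, normalized by the geometric mean of
  the reference RQs, with standard errors propagated in log2 space
  (qBase-style quadrature) and results rescaled so the calibrator sits
  at exactly 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SchemaError, ValidationError

DEFAULT_THRESHOLD_RFU = 75.0
DEFAULT_BASELINE_CYCLES = (1, 5)
MIN_WINDOW = 3
MAX_WINDOW = 5
MIN_WINDOW_R2 = 0.998
# Plateau noise can be collinear by chance; a window must amplify by at
# least this per-cycle factor to count as exponential phase.
MIN_WINDOW_FACTOR = 1.1
MAX_ACCEPTED_FACTOR = 2.2
INTEGRITY_RATIO_LIMIT = 1.5
REGULATION_FOLD = 2.0


@dataclass
class AmplificationCurve:
    """Per-well fluorescence trace; cycles are 1..len(fluorescence)."""

    well_id: str
    target: str
    sample: str
    fluorescence: np.ndarray
    baseline_cycles: tuple[int, int] = DEFAULT_BASELINE_CYCLES
    replicate: int = 1

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if len(self.fluorescence) < 10:
            raise ValidationError(f"well {self.well_id}: need >= 10 cycles")
        if not np.isfinite(self.fluorescence).all():
            raise ValidationError(f"well {self.well_id}: non-finite fluorescence")

    def baseline_subtracted(self) -> np.ndarray:
        lo, hi = self.baseline_cycles
        baseline = self.fluorescence[lo - 1 : hi].mean()
        return self.fluorescence - baseline


@dataclass(frozen=True)
class CqValue:
    well_id: str
    cq: float | None  # None = threshold never crossed

    @property
    def defined(self) -> bool:
        return self.cq is not None


@dataclass(frozen=True)
class WindowFit:
    start_cycle: int
    n_points: int
    slope: float
    r_squared: float
    mean_log_f: float = 0.0

    @property
    def amplification_factor(self) -> float:
        return 10.0 ** self.slope


@dataclass
class EfficiencyEstimate:
    target: str
    amplification_factor: float  # mean over curves
    factor_sd: float
    r_squared: float             # lowest R^2 among chosen windows
    n_points: int                # points in the chosen window (mode)
    n_curves: int
    failed_wells: list[str] = field(default_factory=list)

    @property
    def efficiency(self) -> float:
        return self.amplification_factor - 1.0

    @property
    def accepted(self) -> bool:
        return 1.0 < self.amplification_factor <= MAX_ACCEPTED_FACTOR and self.r_squared >= MIN_WINDOW_R2


@dataclass
class StabilityReport:
    m_values: dict[str, float]           # geNorm M per reference (full panel)
    ranking: list[str]                   # least stable first, selected pair last
    selected_references: tuple[str, str]
    selected_pair_m: float = float("nan")  # M of the finalists (SD of their log2 ratio)


@dataclass(frozen=True)
class NrqResult:
    target: str
    sample: str
    nrq: float
    nrq_se: float
    rescaled: float
    rescaled_se: float


def call_cq(curve: AmplificationCurve, threshold_rfu: float = DEFAULT_THRESHOLD_RFU) -> CqValue:
    """First threshold crossing of the baseline-subtracted trace.

    Interpolation between the bracketing cycles is linear in log
    fluorescence when both values are positive (exact for exponential
    growth), falling back to linear otherwise.
    """
    if threshold_rfu <= 0:
        raise ValidationError("threshold must be positive")
    f = curve.baseline_subtracted()
    above = np.nonzero(f >= threshold_rfu)[0]
    if len(above) == 0:
        return CqValue(curve.well_id, None)
    i = int(above[0])
    if i == 0:
        return CqValue(curve.well_id, 1.0)
    f_lo, f_hi = f[i - 1], f[i]
    if f_lo > 0 and f_hi > 0:
        frac = (np.log(threshold_rfu) - np.log(f_lo)) / (np.log(f_hi) - np.log(f_lo))
    else:
        frac = (threshold_rfu - f_lo) / (f_hi - f_lo)
    return CqValue(curve.well_id, float(i + frac))  # cycles are 1-based


def _window_fits(log_f: np.ndarray, cycles: np.ndarray) -> list[WindowFit]:
    fits = []
    for width in range(MIN_WINDOW, MAX_WINDOW + 1):
        for start in range(0, len(cycles) - width + 1):
            x = cycles[start : start + width]
            y = log_f[start : start + width]
            res = stats.linregress(x, y)
            fits.append(WindowFit(int(x[0]), width, float(res.slope), float(res.rvalue**2), float(y.mean())))
    return fits


def best_window(curve: AmplificationCurve) -> WindowFit | None:
    """Highest-placed rising 3-5 point log-linear window with R^2 >= 0.998.

    Among eligible windows the one with the greatest mean log
    fluorescence is chosen (ties: more points, then higher R^2) — the
    top of the exponential phase, just below the plateau.  Estimating
    the baseline from the early cycles leaves a small constant error
    that artificially steepens log fluorescence near the baseline, so
    low-lying windows overstate the slope; high-lying windows are
    immune because the residual constant is negligible against the
    signal, and windows reaching into the plateau fail the R^2 gate.
    """
    f = curve.baseline_subtracted()
    cycles = np.arange(1, len(f) + 1)
    positive = f > 0
    log_f = np.where(positive, np.log10(np.where(positive, f, 1.0)), np.nan)
    # fit only maximal runs of positive values
    candidates: list[WindowFit] = []
    for _, run in itertools.groupby(range(len(f)), key=lambda i: positive[i]):
        idx = list(run)
        if not positive[idx[0]] or len(idx) < MIN_WINDOW:
            continue
        candidates.extend(_window_fits(log_f[idx], cycles[idx]))
    min_slope = np.log10(MIN_WINDOW_FACTOR)
    eligible = [w for w in candidates if w.r_squared >= MIN_WINDOW_R2 and w.slope >= min_slope]
    if not eligible:
        return None
    return max(eligible, key=lambda w: (w.mean_log_f, w.n_points, w.r_squared))


def estimate_efficiency(curves: list[AmplificationCurve]) -> EfficiencyEstimate:
    """Mean +- SD amplification factor across one target's curves."""
    if not curves:
        raise ValidationError("need at least one curve")
    target = curves[0].target
    factors, r2s, npoints, failed = [], [], [], []
    for curve in curves:
        window = best_window(curve)
        if window is None:
            failed.append(curve.well_id)
            continue
        factors.append(window.amplification_factor)
        r2s.append(window.r_squared)
        npoints.append(window.n_points)
    if not factors:
        raise ValidationError(f"target {target}: no curve has a window with R^2 >= {MIN_WINDOW_R2}")
    return EfficiencyEstimate(
        target=target,
        amplification_factor=float(np.mean(factors)),
        factor_sd=float(np.std(factors, ddof=1)) if len(factors) > 1 else 0.0,
        r_squared=float(min(r2s)),
        n_points=int(stats.mode(np.array(npoints), keepdims=False).mode),
        n_curves=len(factors),
        failed_wells=failed,
    )


def three_five_ratio(cq_3prime: CqValue, cq_5prime: CqValue, factor: float) -> float:
    """Comparative-Cq 3':5' integrity ratio = factor^(Cq5 - Cq3)."""
    if not (cq_3prime.defined and cq_5prime.defined):
        raise ValidationError("both Cq values must be defined for the 3':5' ratio")
    return float(factor ** (cq_5prime.cq - cq_3prime.cq))


def integrity_pass(ratio: float, limit: float = INTEGRITY_RATIO_LIMIT) -> bool:
    return ratio < limit


def relative_quantities(cq_matrix: pd.DataFrame, factors: dict[str, float]) -> pd.DataFrame:
    """q = factor^(minCq - Cq) per reference (rows refs, columns samples)."""
    rows = {}
    for ref in cq_matrix.index:
        cq = cq_matrix.loc[ref].astype(float)
        rows[ref] = factors[ref] ** (cq.min() - cq)
    return pd.DataFrame(rows).T


def genorm_m(cq_matrix: pd.DataFrame, factors: dict[str, float]) -> StabilityReport:
    """geNorm stability over a references x samples Cq matrix.

    M for each reference is the mean over the other references of the
    SD across samples of the pairwise log2 quantity ratio; references
    are removed worst-first until two remain (the selected pair).
    """
    refs = list(cq_matrix.index)
    if len(refs) < 2:
        raise ValidationError("geNorm needs at least 2 references")
    if cq_matrix.shape[1] < 2:
        raise ValidationError("geNorm needs at least 2 samples")
    q = relative_quantities(cq_matrix, factors)
    logq = np.log2(q)

    def m_values(active: list[str]) -> dict[str, float]:
        out = {}
        for j in active:
            sds = [
                float((logq.loc[j] - logq.loc[k]).std(ddof=1))
                for k in active if k != j
            ]
            out[j] = float(np.mean(sds))
        return out

    full = m_values(refs)
    active = list(refs)
    eliminated: list[str] = []
    while len(active) > 2:
        current = m_values(active)
        worst = max(active, key=lambda r: (current[r], r))
        active.remove(worst)
        eliminated.append(worst)
    pair = tuple(sorted(active))
    pair_m = m_values(list(pair))[pair[0]]  # symmetric for two references
    return StabilityReport(
        m_values=full,
        ranking=eliminated + sorted(active),
        selected_references=pair,
        selected_pair_m=pair_m,
    )


def _group_stats(cq: pd.DataFrame) -> pd.DataFrame:
    """Mean Cq and SE (SD/sqrt(n)) per (target, sample) replicate group."""
    grouped = cq.groupby(["target", "sample"])["cq"]
    out = grouped.agg(mean_cq="mean", sd="std", n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    out["se_cq"] = out["sd"] / np.sqrt(out["n"])
    return out


def compute_nrq(
    cq: pd.DataFrame,
    efficiencies: dict[str, float],
    references: list[str],
    calibrator_sample: str,
) -> list[NrqResult]:
    """Efficiency-corrected, multi-reference-normalized relative quantities.

    *cq* is long-format with columns target, sample, replicate, cq.
    *efficiencies* maps every target to its amplification factor.
    Standard errors propagate in log2 space as
    sqrt(SE_goi^2 + (1/R^2) * sum SE_ref^2) over R references, each
    per-group SE being (SD/sqrt(n)) * log2(factor).
    """
    required = {"target", "sample", "replicate", "cq"}
    missing = required - set(cq.columns)
    if missing:
        raise SchemaError(f"Cq table missing column(s): {', '.join(sorted(missing))}")
    targets = list(dict.fromkeys(cq["target"]))
    samples = list(dict.fromkeys(cq["sample"]))
    for t in targets:
        if t not in efficiencies:
            raise ValidationError(f"no efficiency for target {t!r}")
    for r in references:
        if r not in targets:
            raise ValidationError(f"reference {r!r} has no Cq data")
    if calibrator_sample not in samples:
        raise ValidationError(f"calibrator sample {calibrator_sample!r} has no Cq data")
    g = _group_stats(cq).set_index(["target", "sample"])
    for t in targets:
        for s in samples:
            if (t, s) not in g.index:
                raise ValidationError(f"missing replicate group: target {t!r}, sample {s!r}")

    def rq(target: str, sample: str) -> float:
        factor = efficiencies[target]
        return float(factor ** (g.loc[(target, calibrator_sample), "mean_cq"] - g.loc[(target, sample), "mean_cq"]))

    def se_log2(target: str, sample: str) -> float:
        return float(g.loc[(target, sample), "se_cq"] * np.log2(efficiencies[target]))

    n_refs = len(references)
    results: list[NrqResult] = []
    goi_targets = [t for t in targets if t not in references] or targets
    for target in goi_targets:
        per_sample: dict[str, tuple[float, float]] = {}
        for sample in samples:
            norm_factor = float(np.exp(np.mean([np.log(rq(r, sample)) for r in references])))
            nrq = rq(target, sample) / norm_factor
            se = float(
                np.sqrt(
                    se_log2(target, sample) ** 2
                    + sum(se_log2(r, sample) ** 2 for r in references) / n_refs**2
                )
            )
            per_sample[sample] = (nrq, se)
        cal_nrq = per_sample[calibrator_sample][0]
        for sample in samples:
            nrq, se_log = per_sample[sample]
            nrq_se = nrq * np.log(2.0) * se_log  # delta method back to linear scale
            rescaled = nrq / cal_nrq
            results.append(
                NrqResult(target, sample, nrq, float(nrq_se), rescaled, float(rescaled * np.log(2.0) * se_log))
            )
    return results


def regulation_flag(nrq_fold: float) -> str:
    """Two-fold regulation call: 'up' (> 2), 'down' (< 0.5) or 'none'."""
    if nrq_fold <= 0:
        raise ValidationError("fold change must be positive")
    if nrq_fold > REGULATION_FOLD:
        return "up"
    if nrq_fold < 1.0 / REGULATION_FOLD:
        return "down"
    return "none"


def curves_from_long(df: pd.DataFrame, baseline_cycles: tuple[int, int] = DEFAULT_BASELINE_CYCLES) -> list[AmplificationCurve]:
    """Long-format (well, target, sample, replicate, cycle, rfu) -> curves."""
    required = {"well", "target", "sample", "cycle", "rfu"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"curve table missing column(s): {', '.join(sorted(missing))}")
    curves = []
    for well, sub in df.groupby("well", sort=False):
        sub = sub.sort_values("cycle")
        curves.append(
            AmplificationCurve(
                well_id=str(well),
                target=str(sub["target"].iloc[0]),
                sample=str(sub["sample"].iloc[0]),
                fluorescence=sub["rfu"].to_numpy(),
                baseline_cycles=baseline_cycles,
                replicate=int(sub["replicate"].iloc[0]) if "replicate" in sub.columns else 1,
            )
        )
    return curves
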