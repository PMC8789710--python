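"""Paired cohort statistics for pre/post valve-replacement index reports.

Small invasive cohorts (n ~ 8) need exact nonparametric inference: paired
pre/post contrasts use the Wilcoxon signed-rank test with the null
distribution enumerated over all 2^n sign assignments (midranks for tied
absolute differences, zero differences discarded and counted); subgroup
contrasts of per-patient deltas use the exact Mann-Whitney U with the
null enumerated over all group assignments.  Correlations are Kendall's
tau-b (tie-corrected) and Pearson's r.  Above the exact-enumeration sizes
both tests fall back to the tie-corrected normal approximation.

Table builders summarize a cohort as mean (+/- SD) pre and post per index
with the paired p value, and as subgroup delta tables; per-patient indices
are computed first and aggregated afterwards (mean of ratios, not ratio
of means).  No multiple-testing correction is applied by default; Holm
adjustment is available as an option.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .indices import IndexReport, analyze_recording

__all__ = [
    "StatResult",
    "CohortTable",
    "cohort_table",
    "paired_wilcoxon",
    "subgroup_delta_test",
    "mann_whitney_exact",
    "kendall_tau_b",
    "pearson_r",
    "build_tables",
    "TABLE_ROWS",
]

EXACT_WILCOXON_MAX_N = 15
EXACT_MWU_MAX_N = 20   # combined group size for full enumeration
ALPHA = 0.05


@dataclass(frozen=True)
class StatResult:
    """Outcome of one hypothesis test or correlation."""

    test: str
    statistic: float
    p: float
    n: int
    estimate: float = math.nan
    note: str = ""

    def __post_init__(self):
        if math.isfinite(self.p) and not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p value out of range: {self.p}")


# ---------------------------------------------------------------------------
# paired Wilcoxon signed-rank


def _midranks(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a, method="average")


@functools.lru_cache(maxsize=4)
def _sign_masks(n: int) -> np.ndarray:
    """All 2^n binary sign assignments as a (2^n, n) float matrix."""
    k = np.arange(2 ** n)[:, None]
    return ((k >> np.arange(n)[None, :]) & 1).astype(float)


def paired_wilcoxon(pre, post) -> StatResult:
    """Exact two-sided Wilcoxon signed-rank test on paired samples.

    Differences post - pre; zeros are discarded (classical convention) and
    their count reported in the note.  For n <= 15 retained pairs the null
    distribution of W+ is enumerated over all sign assignments (midranks
    for tied |d|); beyond that a tie-corrected normal approximation is
    used.  Raises ``ValueError`` when every difference is zero.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    d = post - pre
    nonzero = d != 0
    n_zero = int((~nonzero).sum())
    d = d[nonzero]
    n = d.size
    if n == 0:
        raise ValueError("degenerate pairs: all differences are zero")
    if n < 3:
        raise ValueError(f"need >= 3 nonzero differences, have {n}")
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    m = float(ranks.sum())
    note = f"{n_zero} zero difference(s) discarded" if n_zero else ""

    if n <= EXACT_WILCOXON_MAX_N:
        dist = _sign_masks(n) @ ranks
        dev = abs(w_plus - m / 2.0)
        p = float(np.mean(np.abs(dist - m / 2.0) >= dev - 1e-12))
        method = "wilcoxon-signed-rank-exact"
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(((counts ** 3 - counts)).sum()) / 48.0
        sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (w_plus - mu) / sigma
        p = 2.0 * sps.norm.sf(abs(z))
        method = "wilcoxon-signed-rank-normal"
    return StatResult(
        test=method, statistic=w_plus, p=min(p, 1.0), n=n,
        estimate=float(np.median(d)), note=note,
    )


# ---------------------------------------------------------------------------
# exact Mann-Whitney U


def mann_whitney_exact(x, y) -> StatResult:
    """Two-sided Mann-Whitney U test; exact by enumeration for small samples.

    For combined n <= 20, the null distribution of U is enumerated over all
    C(n, nx) group assignments on the midranks of the pooled sample; beyond
    that the tie-corrected normal approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    rx = float(ranks[:nx].sum())
    u = rx - nx * (nx + 1) / 2.0
    mid = nx * ny / 2.0
    n = nx + ny

    if n <= EXACT_MWU_MAX_N:
        rank_sum_min = 0.0
        dist = np.fromiter(
            (ranks[list(comb)].sum() for comb in itertools.combinations(range(n), nx)),
            dtype=float,
        )
        dist = dist - nx * (nx + 1) / 2.0 + rank_sum_min
        dev = abs(u - mid)
        p = float(np.mean(np.abs(dist - mid) >= dev - 1e-12))
        method = "mann-whitney-exact"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "mann-whitney-normal"
    return StatResult(
        test=method, statistic=float(u), p=min(p, 1.0), n=n,
        estimate=float(np.median(x) - np.median(y)),
    )


# ---------------------------------------------------------------------------
# correlations


def kendall_tau_b(x, y) -> StatResult:
    """Kendall's tau-b with tie correction, two-sided p.

    Degenerate (constant) input yields an undefined estimate, flagged in
    the note rather than silently coerced.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return StatResult(
            test="kendall-tau-b", statistic=math.nan, p=math.nan,
            n=x.size, estimate=math.nan, note="degenerate: constant input",
        )
    res = sps.kendalltau(x, y)
    return StatResult(
        test="kendall-tau-b", statistic=float(res.statistic),
        p=float(res.pvalue), n=x.size, estimate=float(res.statistic),
    )


def pearson_r(x, y) -> StatResult:
    """Pearson product-moment correlation with two-sided t-distribution p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = sps.pearsonr(x, y)
    return StatResult(
        test="pearson-r", statistic=float(res.statistic),
        p=float(res.pvalue), n=x.size, estimate=float(res.statistic),
    )


# ---------------------------------------------------------------------------
# cohort container and tables


@dataclass
class CohortRow:
    patient_id: str
    pre: IndexReport
    post: IndexReport
    labels: dict = field(default_factory=dict)
    covariates: dict = field(default_factory=dict)


@dataclass
class CohortTable:
    """Per-patient paired index reports with subgroup labels."""

    rows: list[CohortRow]

    def __post_init__(self):
        for r in self.rows:
            if r.pre is None or r.post is None:
                raise ValueError(f"patient {r.patient_id}: pre and post must both be present")

    def __len__(self) -> int:
        return len(self.rows)

    def values(self, index: str, phase: str) -> np.ndarray:
        """Per-patient values of one index ('pre' or 'post')."""
        return np.array(
            [getattr(getattr(r, phase), index) for r in self.rows], dtype=float
        )

    def deltas(self, index: str) -> np.ndarray:
        return self.values(index, "post") - self.values(index, "pre")

    def group_mask(self, grouping: str) -> np.ndarray:
        return np.array([bool(r.labels.get(grouping, False)) for r in self.rows])


def cohort_table(patients, n_beats: int = 10, rr_tol="auto", min_beats: int = 6) -> CohortTable:
    """Run the full analysis pipeline on a simulated cohort.

    ``patients`` is the list of :class:`pvloop.hemosim.CohortPatient`; each
    pre and post recording is segmented, cleaned and summarized into an
    :class:`IndexReport`.
    """
    rows = []
    for p in patients:
        rows.append(
            CohortRow(
                patient_id=p.patient_id,
                pre=analyze_recording(p.pre, n_beats=n_beats, rr_tol=rr_tol, min_beats=min_beats),
                post=analyze_recording(p.post, n_beats=n_beats, rr_tol=rr_tol, min_beats=min_beats),
                labels=dict(p.labels),
                covariates=dict(p.covariates),
            )
        )
    return CohortTable(rows)


def subgroup_delta_test(cohort: CohortTable, index: str, grouping: str) -> StatResult:
    """Exact Mann-Whitney U on per-patient deltas (post - pre) between the
    subgroup carrying ``grouping`` and the rest."""
    mask = cohort.group_mask(grouping)
    d = cohort.deltas(index)
    if mask.all() or not mask.any():
        raise ValueError(f"grouping {grouping!r} yields an empty group")
    return mann_whitney_exact(d[mask], d[~mask])


# row label -> (IndexReport attribute, display scale)
TABLE_ROWS: dict[str, tuple[str, float]] = {
    "HR (beats/min)": ("hr", 1.0),
    "EF (%)": ("ef", 100.0),
    "SV (ml)": ("sv", 1.0),
    "SVI (ml/m^2)": ("svi", 1.0),
    "SW (mmHg ml)": ("sw", 1.0),
    "CO (l/min)": ("co", 1.0),
    "CI (l/min/m^2)": ("ci", 1.0),
    "EDV (ml)": ("edv", 1.0),
    "ESV (ml)": ("esv", 1.0),
    "EDP (mmHg)": ("edp", 1.0),
    "ESP (mmHg)": ("esp", 1.0),
    "PRSW (mmHg)": ("prsw", 1.0),
    "dP/dt+ (mmHg/s)": ("dpdt_max", 1.0),
    "dP/dt- (mmHg/s)": ("dpdt_min", 1.0),
    "TAU (ms)": ("tau_half_ms", 1.0),
    "End-systolic elastance (mmHg/ml)": ("ees", 1.0),
    "SCI (mmHg/ml s)": ("sci", 1.0),
    "Arterial elastance (mmHg/ml)": ("ea", 1.0),
    "Valvulo-arterial impedance (mmHg m^2/ml)": ("zva", 1.0),
    "End-diastolic stiffness (mmHg/ml)": ("eed", 1.0),
    "Ventricular-arterial coupling (Ea/Ees)": ("vac_ea_over_ees", 1.0),
    "Ventricular-arterial coupling (Ees/Ea)": ("vac_ees_over_ea", 1.0),
}


def build_tables(cohort: CohortTable, holm: bool = False) -> dict[str, pd.DataFrame]:
    """Mean (+/- SD) pre/post summary with paired p values, and subgroup
    delta tables for each label present in the cohort.

    With a single patient, SDs are reported as NaN and no tests are run.
    Significance markers appear iff the (optionally Holm-adjusted) paired
    p is below 0.05.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rows = []
    pvals = {}
    for label, (attr, scale) in TABLE_ROWS.items():
        pre = cohort.values(attr, "pre") * scale
        post = cohort.values(attr, "post") * scale
        entry = {
            "index": label,
            "pre_mean": float(np.nanmean(pre)),
            "pre_sd": float(np.nanstd(pre, ddof=1)) if len(cohort) > 1 else math.nan,
            "post_mean": float(np.nanmean(post)),
            "post_sd": float(np.nanstd(post, ddof=1)) if len(cohort) > 1 else math.nan,
        }
        if len(cohort) > 1:
            try:
                res = paired_wilcoxon(pre, post)
                entry["p"] = res.p
                pvals[label] = res.p
            except ValueError as e:
                entry["p"] = math.nan
                entry["note"] = str(e)
        else:
            entry["p"] = math.nan
        rows.append(entry)
    summary = pd.DataFrame(rows).set_index("index")
    if holm and pvals:
        labels = list(pvals)
        adj = _holm(np.array([pvals[k] for k in labels]))
        summary.loc[labels, "p_holm"] = adj
        summary["significant"] = summary.get("p_holm", summary["p"]) < ALPHA
    else:
        summary["significant"] = summary["p"] < ALPHA

    out = {"summary": summary}
    if len(cohort) > 1:
        groupings = sorted({g for r in cohort.rows for g in r.labels})
        for g in groupings:
            mask = cohort.group_mask(g)
            if not mask.any() or mask.all():
                continue
            grows = []
            for label, (attr, scale) in TABLE_ROWS.items():
                d = cohort.deltas(attr) * scale
                entry = {
                    "index": label,
                    f"{g}_mean": float(np.nanmean(d[mask])),
                    f"{g}_sd": float(np.nanstd(d[mask], ddof=1)) if mask.sum() > 1 else math.nan,
                    f"not_{g}_mean": float(np.nanmean(d[~mask])),
                    f"not_{g}_sd": float(np.nanstd(d[~mask], ddof=1)) if (~mask).sum() > 1 else math.nan,
                }
                try:
                    entry["p"] = mann_whitney_exact(d[mask], d[~mask]).p
                except ValueError as e:
                    entry["p"] = math.nan
                    entry["note"] = str(e)
                grows.append(entry)
            df = pd.DataFrame(grows).set_index("index")
            df["significant"] = df["p"] < ALPHA
            out[f"delta_by_{g}"] = df
    return out


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj
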