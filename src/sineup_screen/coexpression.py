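"""Expression-side statistics for sense/antisense pairs.

Covers the three quantitative read-outs used alongside the structural
screen: relative qPCR quantification by the 2^-ddCq method (target Cq
normalised to a reference gene, then to a calibrator sample), a
tissue-panel matrix where each gene is scaled to its highest-expressing
tissue (heatmap-ready, values in (0, 1]), and simple sense/antisense vs
regulator regressions (OLS slope, Pearson r, R², two-sided slope p),
optionally per sample group.

Replicates are averaged on the Cq (cycle) scale before any differencing,
the standard ddCq practice; exponentiation to the linear scale happens
last.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("sineup_screen")


@dataclass
class CqTable:
    """Long-format qPCR quantification cycles.

    ``data`` columns: sample, gene, replicate, cq. The reference gene
    (e.g. NONO) is the within-sample normaliser; the calibrator sample is
    the between-sample baseline (its relative expression is exactly 1).
    """

    data: pd.DataFrame
    reference_gene: str
    calibrator_sample: str

    def __post_init__(self) -> None:
        required = {"sample", "gene", "replicate", "cq"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"CqTable missing columns: {sorted(missing)}")
        if (self.data["cq"] <= 0).any():
            raise ValueError("Cq values must be positive")
        if self.calibrator_sample not in set(self.data["sample"]):
            raise ValueError(f"calibrator sample {self.calibrator_sample!r} absent")


@dataclass
class RelExpressionResult:
    """Per (sample, gene) dCq, ddCq and relative expression 2^-ddCq."""

    data: pd.DataFrame  # columns: sample, gene, delta_cq, delta_delta_cq, rel_expr
    reference_gene: str
    calibrator_sample: str

    def rel_expr(self, sample: str, gene: str) -> float:
        sel = self.data[(self.data["sample"] == sample) & (self.data["gene"] == gene)]
        if sel.empty:
            raise KeyError((sample, gene))
        return float(sel["rel_expr"].iloc[0])


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with its unit and sample groups."""

    values: pd.DataFrame  # index: genes, columns: samples
    unit: str  # CPM | logCPM | rel_expr
    sample_groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in ("CPM", "logCPM", "rel_expr"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.unit in ("CPM", "rel_expr") and (self.values.values < 0).any():
            raise ValueError(f"negative values in a {self.unit} matrix")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    p_value: float  # two-sided, H0: slope = 0
    n: int


@dataclass
class PairRegression:
    overall: RegressionResult
    by_group: dict[str, RegressionResult] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# 2^-ddCq
# ---------------------------------------------------------------------------

def delta_delta_cq(cq: CqTable) -> RelExpressionResult:
    """Relative expression by the 2^-ddCq method.

    Per sample: dCq = mean Cq(target) - mean Cq(reference) (replicate
    means taken on the Cq scale). Per gene: ddCq = dCq(sample) -
    dCq(calibrator); relative expression is 2^-ddCq, so the calibrator
    sample is exactly 1. Samples missing the reference gene are skipped
    with a warning.
    """
    means = (
        cq.data.groupby(["sample", "gene"], sort=True)["cq"].mean().unstack("gene")
    )
    if cq.reference_gene not in means.columns:
        raise ValueError(f"reference gene {cq.reference_gene!r} absent from table")
    ref = means[cq.reference_gene]
    usable = ref.notna()
    for sample in means.index[~usable]:
        log.warning("sample %s skipped: no reference-gene Cq", sample)
    means = means.loc[usable]
    ref = ref.loc[usable]
    if cq.calibrator_sample not in means.index:
        raise ValueError("calibrator sample lost (no reference-gene Cq)")

    rows = []
    targets = [g for g in means.columns if g != cq.reference_gene]
    for gene in targets:
        dcq = means[gene] - ref
        cal = dcq.loc[cq.calibrator_sample]
        if pd.isna(cal):
            log.warning("gene %s absent from calibrator sample; dropped", gene)
            continue
        ddcq = dcq - cal
        for sample in means.index:
            if pd.isna(dcq.loc[sample]):
                continue
            rows.append({
                "sample": sample,
                "gene": gene,
                "delta_cq": float(dcq.loc[sample]),
                "delta_delta_cq": float(ddcq.loc[sample]),
                "rel_expr": float(2.0 ** -ddcq.loc[sample]),
            })
    return RelExpressionResult(
        data=pd.DataFrame(rows, columns=["sample", "gene", "delta_cq",
                                         "delta_delta_cq", "rel_expr"]),
        reference_gene=cq.reference_gene,
        calibrator_sample=cq.calibrator_sample,
    )


def tissue_relative_matrix(rel: RelExpressionResult) -> ExpressionMatrix:
    """Per-gene max-relative expression across a tissue panel.

    Each gene's relative-expression values are rescaled so its
    highest-expressing tissue equals 1.0 — equivalent to taking the ddCq
    baseline at the minimum dCq tissue. Genes with no finite value are
    dropped with a warning. Output is heatmap-ready (genes x tissues,
    values in (0, 1]).
    """
    wide = rel.data.pivot(index="gene", columns="sample", values="rel_expr")
    keep = []
    for gene, row in wide.iterrows():
        if row.notna().any():
            keep.append(gene)
        else:
            log.warning("gene %s dropped: no expression values", gene)
    wide = wide.loc[keep]
    scaled = wide.div(wide.max(axis=1), axis=0)
    return ExpressionMatrix(values=scaled, unit="rel_expr")


# ---------------------------------------------------------------------------
# Regressions and group tests
# ---------------------------------------------------------------------------

def _regress(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError(f"need >=3 paired finite observations, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: zero variance in x")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        r_squared=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
        n=int(x.size),
    )


def pair_regression(
    m: ExpressionMatrix,
    x_gene: str,
    y_gene: str,
    groups: pd.Series | None = None,
) -> PairRegression:
    """OLS of ``y_gene`` on ``x_gene`` across samples, overall and per group.

    ``groups`` (sample -> label; defaults to ``m.sample_groups``) adds one
    fitted result per label, as when contrasting cases and controls.
    """
    for gene in (x_gene, y_gene):
        if gene not in m.values.index:
            raise KeyError(f"gene {gene!r} not in matrix")
    x = m.values.loc[x_gene].to_numpy(dtype=float)
    y = m.values.loc[y_gene].to_numpy(dtype=float)
    result = PairRegression(overall=_regress(x, y))
    groups = groups if groups is not None else m.sample_groups
    if groups is not None:
        labels = groups.reindex(m.values.columns)
        for label in sorted(labels.dropna().unique()):
            sel = (labels == label).to_numpy()
            result.by_group[str(label)] = _regress(x[sel], y[sel])
    return result


def group_t_test(
    a: np.ndarray | list,
    b: np.ndarray | list,
    one_tailed: bool = True,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Unpaired Student's t-test between two sample groups.

    Defaults to a one-tailed test (``alternative`` names the direction of
    ``a`` relative to ``b``); set ``one_tailed=False`` for two-sided.
    Returns (t statistic, p value).
    """
    alt = alternative if one_tailed else "two-sided"
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                          alternative=alt)
    return float(res.statistic), float(res.pvalue)


def load_expression_matrix(
    path, unit: str, groups: pd.Series | None = None
) -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column = gene ids) as a matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=df, unit=unit, sample_groups=groups)
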