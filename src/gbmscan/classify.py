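"""Binomial mCG-enrichment classification of genes (gbM calling).

For each gene and sequence context the pooled methylated read count is
tested against a context-specific background — the weighted methylation of
all coding sequence — with a one-sided exact binomial test, and p-values are
Benjamini–Hochberg adjusted per context across genes. A gene is called gbM
(gene-body methylated / mCG-enriched) when reads map to at least 10 CG
sites, the CG q-value is below alpha, and the CHG and CHH q-values are above
alpha. The remaining labels (mCHG_enriched, mCHH_enriched, multi_context,
unmethylated, unclassified) are reporting conveniences derived from the same
q-values.

The binomial unit is READS by default (pooled methylated vs total reads per
gene), which stays defined at ~1× coverage; a per-site mode (sites with a
methylated read vs covered sites) is available via ``unit="sites"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONTEXTS
from .metrics import assign_to_genes, summarize_genes

EPS = 1e-9

LABELS = (
    "gbM",
    "mCHG_enriched",
    "mCHH_enriched",
    "multi_context",
    "unmethylated",
    "unclassified",
)


@dataclass(frozen=True)
class BackgroundLevels:
    """Per-context background methylation proportion over all coding
    sequence, with the read totals it was computed from. Proportions are
    clamped to [eps, 1−eps] so the binomial test is always defined."""

    p0: dict[str, float]
    mc: dict[str, int]
    cov: dict[str, int]

    def __getitem__(self, context: str) -> float:
        return self.p0[context]


def estimate_background(records: pd.DataFrame, genes: pd.DataFrame) -> BackgroundLevels:
    """Weighted methylation per context over the union of coding intervals."""
    gi = assign_to_genes(records, genes)
    coding = records.loc[gi >= 0]
    p0, mcs, covs = {}, {}, {}
    for ctx in CONTEXTS:
        sub = coding[coding["context"] == ctx]
        mc, cov = int(sub["mc"].sum()), int(sub["cov"].sum())
        if cov == 0:
            raise ValueError(
                f"no {ctx} coverage in coding sequence; supply an explicit "
                f"background (e.g. --background {ctx}=<p0>)"
            )
        p0[ctx] = float(np.clip(mc / cov, EPS, 1.0 - EPS))
        mcs[ctx], covs[ctx] = mc, cov
    return BackgroundLevels(p0, mcs, covs)


def binomial_enrichment_p(k, n, p0):
    """One-sided upper-tail exact binomial p-value P(X ≥ k), X~Bin(n, p0).

    Vectorised over k and n; entries with n = 0 return NaN (no test).
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("need 0 ≤ k ≤ n")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0,1)")
    with np.errstate(invalid="ignore"):
        p = stats.binom.sf(k - 1, n, p0)
    p = np.where(n == 0, np.nan, np.minimum(p, 1.0))
    return float(p) if p.ndim == 0 else p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values; NaN entries pass through.

    Sorting ascending, q_(i) = min_{j≥i} m·p_(j)/j capped at 1, mapped back
    to input order; monotone in p.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if m:
        pv = p[ok]
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / np.arange(1, m + 1)
        qv = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
        out = np.empty(m)
        out[order] = qv
        q[ok] = out
    return q


class GbmEnrichmentModel:
    """Binomial mCG-enrichment model over a set of gene summaries.

    Parameters
    ----------
    summaries : DataFrame
        Per-gene per-context counts as produced by
        :func:`gbmscan.metrics.summarize_genes`.
    background : BackgroundLevels or mapping context → p0
        Context-specific background proportions.
    alpha : float
        FDR threshold (default 0.05).
    min_cg_sites : int
        Minimum covered CG sites for a gene to be classifiable (default 10).
    unit : {"reads", "sites"}
        Binomial unit: pooled reads (default) or methylated-call sites.
    strict_noncg : bool
        When True a gene needs defined, non-significant CHG and CHH tests to
        be gbM; default treats undefined non-CG tests as not enriched so
        sparse genes remain classifiable.
    fdr_scope : {"per_context", "joint"}
        Whether BH spans genes within each context or genes × contexts.
    """

    def __init__(
        self,
        summaries: pd.DataFrame,
        background,
        alpha: float = 0.05,
        min_cg_sites: int = 10,
        unit: str = "reads",
        strict_noncg: bool = False,
        fdr_scope: str = "per_context",
    ):
        if summaries.empty:
            raise ValueError("no gene summaries to classify")
        if unit not in ("reads", "sites"):
            raise ValueError("unit must be 'reads' or 'sites'")
        if fdr_scope not in ("per_context", "joint"):
            raise ValueError("fdr_scope must be 'per_context' or 'joint'")
        self.summaries = summaries.reset_index(drop=True)
        if not isinstance(background, BackgroundLevels):
            background = BackgroundLevels(
                {c: float(np.clip(background[c], EPS, 1 - EPS)) for c in CONTEXTS},
                {c: 0 for c in CONTEXTS},
                {c: 0 for c in CONTEXTS},
            )
        self.background = background
        self.alpha = alpha
        self.min_cg_sites = min_cg_sites
        self.unit = unit
        self.strict_noncg = strict_noncg
        self.fdr_scope = fdr_scope

    @classmethod
    def from_records(cls, records: pd.DataFrame, genes: pd.DataFrame, background=None, **kw):
        """Build the model straight from cytosine records and gene models."""
        summaries = summarize_genes(records, genes)
        if background is None:
            background = estimate_background(records, genes)
        return cls(summaries, background, **kw)

    def _counts(self, ctx: str) -> tuple[np.ndarray, np.ndarray]:
        s = self.summaries
        if self.unit == "reads":
            return s[f"{ctx}_mc"].to_numpy(), s[f"{ctx}_cov"].to_numpy()
        if f"{ctx}_meth_sites" not in s:
            raise ValueError(f"unit='sites' needs a {ctx}_meth_sites column in summaries")
        return s[f"{ctx}_meth_sites"].to_numpy(), s[f"{ctx}_sites"].to_numpy()

    def fit(self) -> "GbmClassificationResults":
        """Run the tests, adjust, and label every gene."""
        s = self.summaries
        table = pd.DataFrame({"gene_id": s["gene_id"]})
        pcols = {}
        for ctx in CONTEXTS:
            k, n = self._counts(ctx)
            p = binomial_enrichment_p(k, n, self.background[ctx])
            table[f"{ctx}_sites"] = s[f"{ctx}_sites"]
            table[f"{ctx}_mc"] = s[f"{ctx}_mc"]
            table[f"{ctx}_cov"] = s[f"{ctx}_cov"]
            table[f"{ctx}_p"] = p
            pcols[ctx] = p
        if self.fdr_scope == "joint":
            stacked = np.concatenate([pcols[c] for c in CONTEXTS])
            qs = bh_adjust(stacked).reshape(len(CONTEXTS), -1)
            for i, ctx in enumerate(CONTEXTS):
                table[f"{ctx}_q"] = qs[i]
        else:
            for ctx in CONTEXTS:
                table[f"{ctx}_q"] = bh_adjust(pcols[ctx])

        alpha = self.alpha
        qcg = table["CG_q"].to_numpy()
        sig = {ctx: table[f"{ctx}_q"].to_numpy() < alpha for ctx in CONTEXTS}
        undef_noncg = {ctx: np.isnan(table[f"{ctx}_q"].to_numpy()) for ctx in ("CHG", "CHH")}
        classifiable = table["CG_sites"].to_numpy() >= self.min_cg_sites
        # undefined CG p (zero reads) cannot support any call
        classifiable &= ~np.isnan(qcg)

        noncg_clear = ~sig["CHG"] & ~sig["CHH"]
        if self.strict_noncg:
            noncg_clear &= ~undef_noncg["CHG"] & ~undef_noncg["CHH"]
        n_sig = sum(np.where(np.isnan(table[f"{ctx}_q"].to_numpy()), False, sig[ctx]) for ctx in CONTEXTS)

        label = np.full(len(table), "unclassified", dtype=object)
        label[classifiable & (n_sig == 0)] = "unmethylated"
        label[classifiable & (n_sig >= 2)] = "multi_context"
        label[classifiable & sig["CG"] & noncg_clear] = "gbM"
        only_chg = classifiable & sig["CHG"] & ~sig["CG"] & ~sig["CHH"]
        only_chh = classifiable & sig["CHH"] & ~sig["CG"] & ~sig["CHG"]
        label[only_chg] = "mCHG_enriched"
        label[only_chh] = "mCHH_enriched"
        # strict mode: CG-significant genes with undefined non-CG tests fall
        # back to multi_context-free bucket "unclassified"
        if self.strict_noncg:
            blocked = classifiable & sig["CG"] & ~sig["CHG"] & ~sig["CHH"] & (
                undef_noncg["CHG"] | undef_noncg["CHH"]
            )
            label[blocked] = "unclassified"
        table["label"] = label
        return GbmClassificationResults(self, table)


@dataclass
class GbmClassificationResults:
    """Fitted classification: per-gene p/q-values and labels.

    ``table`` has one row per gene: gene_id, per-context sites/mc/cov/p/q,
    and the final label.
    """

    model: GbmEnrichmentModel
    table: pd.DataFrame

    @property
    def labels(self) -> pd.Series:
        return self.table.set_index("gene_id")["label"]

    def label_counts(self) -> pd.Series:
        counts = self.table["label"].value_counts()
        return counts.reindex(LABELS, fill_value=0)

    def gbm_genes(self) -> list[str]:
        return self.table.loc[self.table["label"] == "gbM", "gene_id"].tolist()

    def summary(self) -> str:
        bg = self.model.background
        lines = [
            "Binomial mCG-enrichment classification",
            "=" * 46,
            f"genes tested        : {len(self.table)}",
            f"alpha (BH FDR)      : {self.model.alpha}",
            f"min covered CG sites: {self.model.min_cg_sites}",
            f"binomial unit       : {self.model.unit}",
            f"FDR scope           : {self.model.fdr_scope}",
            "background p0       : "
            + ", ".join(f"{c}={bg[c]:.6g}" for c in CONTEXTS),
            "-" * 46,
        ]
        for lab, n in self.label_counts().items():
            lines.append(f"{lab:<16}: {n}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def classify_genes(
    summaries: pd.DataFrame,
    background,
    alpha: float = 0.05,
    min_cg_sites: int = 10,
    **kw,
) -> pd.DataFrame:
    """Functional wrapper: classification table for gene summaries."""
    model = GbmEnrichmentModel(summaries, background, alpha=alpha, min_cg_sites=min_cg_sites, **kw)
    return model.fit().table
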