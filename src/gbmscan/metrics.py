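"""Weighted methylation at genome, gene and window resolution.

Weighted methylation over a region and context is Σ methylated reads divided
by Σ (methylated + unmethylated) reads — coverage-weighted and therefore
stable at low depth. Metagene profiles divide each gene body (start to stop
codon) into 20 windows and, optionally, 1000- or 4000-bp flanks into 20
windows each; the profile value for a window is the unweighted mean of
per-gene weighted levels across genes with coverage in that window, after
reorienting minus-strand genes 5'→3'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CONTEXTS
from .simulate import N_BODY_WINDOWS, _body_window

UNDEFINED = float("nan")


def assign_to_genes(records: pd.DataFrame, genes: pd.DataFrame) -> np.ndarray:
    """Index of the gene containing each record, −1 when intergenic.

    Genes must be sorted by (chrom, start) and non-overlapping per
    chromosome, as produced by the readers and the simulator.
    """
    out = np.full(len(records), -1, dtype=np.int64)
    for chrom, sub in genes.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if (starts[1:] <= ends[:-1]).any():
            raise ValueError(f"overlapping genes on {chrom}")
        mask = (records["chrom"] == chrom).to_numpy()
        pos = records.loc[mask, "pos"].to_numpy()
        gi = np.searchsorted(starts, pos, side="right") - 1
        inside = (gi >= 0) & (pos <= ends[np.clip(gi, 0, None)])
        out[np.flatnonzero(mask)[inside]] = sub.index.to_numpy()[gi[inside]]
    return out


def weighted_methylation(
    records: pd.DataFrame,
    context: str | None = None,
    chrom: str | None = None,
    start: int | None = None,
    end: int | None = None,
) -> float:
    """Weighted methylation level of a region (whole genome by default).

    Returns NaN — never 0 — when no read covers the region in the requested
    context.
    """
    df = records
    if context is not None:
        df = df[df["context"] == context]
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    if start is not None:
        df = df[df["pos"] >= start]
    if end is not None:
        df = df[df["pos"] <= end]
    total = int(df["cov"].sum())
    if total == 0:
        return UNDEFINED
    return float(df["mc"].sum()) / total


def summarize_genes(records: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-context coverage and weighted methylation.

    Returns one row per gene (in annotation order) with, per context,
    ``{ctx}_sites`` (cytosines with ≥1 read), ``{ctx}_mc``, ``{ctx}_cov`` and
    ``{ctx}_level`` = mc/cov (NaN when cov = 0). Genes on chromosomes absent
    from the records get all-zero coverage.
    """
    gi = assign_to_genes(records, genes)
    inside = gi >= 0
    df = records.loc[inside, ["context", "mc", "cov"]].copy()
    df["gene"] = gi[inside]
    agg = (
        df.assign(
            covered=(df["cov"] > 0).astype(np.int64),
            called=(df["mc"] > 0).astype(np.int64),
        )
        .groupby(["gene", "context"], sort=False)
        .agg(
            sites=("covered", "sum"),
            meth_sites=("called", "sum"),
            mc=("mc", "sum"),
            cov=("cov", "sum"),
        )
        .unstack("context", fill_value=0)
    )
    out = pd.DataFrame({"gene_id": genes["gene_id"].to_numpy()})
    for ctx in CONTEXTS:
        for col in ("sites", "meth_sites", "mc", "cov"):
            vals = np.zeros(len(genes), dtype=np.int64)
            if (col, ctx) in agg.columns:
                vals[agg.index.to_numpy()] = agg[(col, ctx)].to_numpy()
            out[f"{ctx}_{col}"] = vals
    for ctx in CONTEXTS:
        cov = out[f"{ctx}_cov"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"{ctx}_level"] = np.where(cov > 0, out[f"{ctx}_mc"] / cov, UNDEFINED)
    return out


@dataclass
class MetaplotProfile:
    """Mean metagene methylation profile.

    ``values[ctx]`` is a vector of per-window means (5'→3': 20 upstream
    windows when flanks are requested, 20 body windows, 20 downstream), and
    ``n_genes[ctx]`` the number of genes contributing to each mean.
    ``gene_levels[ctx]`` keeps the per-gene window matrix used for
    resampling.
    """

    flank_bp: int
    contexts: tuple[str, ...]
    values: dict[str, np.ndarray]
    n_genes: dict[str, np.ndarray]
    gene_levels: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def n_windows(self) -> int:
        return next(iter(self.values.values())).size

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: window_index, region (up/body/down), context,
        mean_level, n_genes."""
        rows = []
        with_flanks = self.n_windows == 3 * N_BODY_WINDOWS
        for ctx in self.contexts:
            for w, (v, n) in enumerate(zip(self.values[ctx], self.n_genes[ctx])):
                if with_flanks:
                    region = ("up", "body", "down")[w // N_BODY_WINDOWS]
                    idx = w % N_BODY_WINDOWS
                else:
                    region, idx = "body", w
                rows.append(
                    {"window_index": idx, "region": region, "context": ctx,
                     "mean_level": v, "n_genes": int(n)}
                )
        return pd.DataFrame(rows)

    def plot(self, ax=None):
        """One line per context; vertical lines mark the TSS and TTS."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3.2))
        x = np.arange(self.n_windows)
        for ctx in self.contexts:
            ax.plot(x, self.values[ctx], label=f"m{ctx}")
        if self.n_windows == 3 * N_BODY_WINDOWS:
            for b, lab in ((N_BODY_WINDOWS, "TSS"), (2 * N_BODY_WINDOWS, "TTS")):
                ax.axvline(b - 0.5, color="grey", lw=0.8, ls="--")
                ax.text(b - 0.5, ax.get_ylim()[1], lab, ha="center", va="bottom")
        ax.set_xlabel("window (5'→3')")
        ax.set_ylabel("weighted methylation")
        ax.legend(frameon=False)
        return ax


def _interval_members(
    pos: np.ndarray, lo: np.ndarray, hi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """For sorted positions, the (interval_index, position_index) pairs of all
    positions inside each closed interval [lo_i, hi_i]. Intervals may overlap:
    a position then appears once per containing interval."""
    left = np.searchsorted(pos, lo, side="left")
    right = np.searchsorted(pos, hi, side="right")
    lens = right - left
    iv = np.repeat(np.arange(lo.size), lens)
    if iv.size == 0:
        return iv, iv.copy()
    offsets = np.arange(lens.sum()) - np.repeat(np.cumsum(lens) - lens, lens)
    return iv, offsets + np.repeat(left, lens)


def _gene_window_levels(
    records: pd.DataFrame,
    genes: pd.DataFrame,
    flank_bp: int,
    contexts: tuple[str, ...],
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Per-gene window-level matrices (genes × windows, NaN = no coverage).

    Flanks overlapping neighbouring genes are not masked: a cytosine counts
    for every gene whose body or flank interval contains it.
    """
    kept = genes[(genes["end"] - genes["start"] + 1) >= N_BODY_WINDOWS].reset_index(drop=True)
    if kept.empty:
        raise ValueError("no genes of length ≥ 20 bp to profile")
    n_win = 3 * N_BODY_WINDOWS if flank_bp else N_BODY_WINDOWS
    starts = kept["start"].to_numpy()
    ends = kept["end"].to_numpy()
    lengths = ends - starts + 1
    minus = (kept["strand"] == "-").to_numpy()
    wsize = flank_bp // N_BODY_WINDOWS if flank_bp else 0
    body_off = N_BODY_WINDOWS if flank_bp else 0

    mats = {}
    for ctx in contexts:
        sub = records[records["context"] == ctx]
        mc_mat = np.zeros((len(kept), n_win))
        cov_mat = np.zeros((len(kept), n_win))
        for chrom, gsub in kept.groupby("chrom", sort=False):
            gidx = gsub.index.to_numpy()
            cstarts, cends = starts[gidx], ends[gidx]
            rsub = sub[sub["chrom"] == chrom].sort_values("pos", kind="mergesort")
            pos = rsub["pos"].to_numpy()
            mc = rsub["mc"].to_numpy()
            cov = rsub["cov"].to_numpy()
            # body windows occupy forward-layout slots 20..39 (0..19 sans flanks)
            g, si = _interval_members(pos, cstarts, cends)
            win = _body_window(pos[si] - cstarts[g], lengths[gidx][g])
            np.add.at(mc_mat, (gidx[g], win + body_off), mc[si])
            np.add.at(cov_mat, (gidx[g], win + body_off), cov[si])
            if flank_bp:
                # left flank [start-F, start-1] → slots 0..19
                g, si = _interval_members(pos, cstarts - flank_bp, cstarts - 1)
                win = (pos[si] - (cstarts[g] - flank_bp)) // wsize
                np.add.at(mc_mat, (gidx[g], win), mc[si])
                np.add.at(cov_mat, (gidx[g], win), cov[si])
                # right flank [end+1, end+F] → slots 40..59
                g, si = _interval_members(pos, cends + 1, cends + flank_bp)
                win = (pos[si] - (cends[g] + 1)) // wsize + 2 * N_BODY_WINDOWS
                np.add.at(mc_mat, (gidx[g], win), mc[si])
                np.add.at(cov_mat, (gidx[g], win), cov[si])
        with np.errstate(invalid="ignore", divide="ignore"):
            levels = np.where(cov_mat > 0, mc_mat / cov_mat, np.nan)
        levels[minus] = levels[minus, ::-1]  # reorient minus-strand genes 5'→3'
        mats[ctx] = levels
    return kept, mats


def metaplot(
    records: pd.DataFrame,
    genes: pd.DataFrame,
    flank_bp: int = 1000,
    contexts: tuple[str, ...] = CONTEXTS,
) -> MetaplotProfile:
    """Metagene profile: 20 body windows plus 20-window flanks of
    ``flank_bp`` (0 disables flanks).

    Genes shorter than 20 bp are excluded. The per-window value is the
    unweighted mean over genes with coverage in that window.
    """
    if flank_bp not in (0, 1000, 4000):
        raise ValueError("flank_bp must be 0, 1000 or 4000")
    _, mats = _gene_window_levels(records, genes, flank_bp, contexts)
    values, counts = {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for ctx, levels in mats.items():
            values[ctx] = np.nanmean(levels, axis=0)
            counts[ctx] = (~np.isnan(levels)).sum(axis=0)
    return MetaplotProfile(flank_bp, tuple(contexts), values, counts, mats)


def resampled_metaplot(
    records: pd.DataFrame,
    genes: pd.DataFrame,
    k: int,
    reps: int,
    seed: int,
    flank_bp: int = 1000,
    contexts: tuple[str, ...] = CONTEXTS,
) -> MetaplotProfile:
    """Mean profile over ``reps`` random draws of ``k`` genes (without
    replacement within a draw) — the resampling control used to compare gene
    sets of unequal size."""
    kept, mats = _gene_window_levels(records, genes, flank_bp, contexts)
    if k > len(kept):
        raise ValueError(f"k={k} exceeds subset size {len(kept)}")
    rng = np.random.default_rng(seed)
    draws = [rng.choice(len(kept), size=k, replace=False) for _ in range(reps)]
    values, counts = {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for ctx, levels in mats.items():
            per_draw = np.stack(
                [np.nanmean(levels[d], axis=0) for d in draws]
            )  # draws with no coverage in a window yield NaN and are skipped
            values[ctx] = np.nanmean(per_draw, axis=0)
            counts[ctx] = (~np.isnan(per_draw)).sum(axis=0)
    return MetaplotProfile(flank_bp, tuple(contexts), values, counts, mats)
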