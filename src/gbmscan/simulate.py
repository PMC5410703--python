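"""Ground-truthed synthetic methylome generator.

Emulates the statistical structure of plant whole-genome bisulfite data at
the level the downstream analysis consumes: a single chromosome carrying
non-overlapping genes of three methylation classes —

* ``gbM``       : CG methylation enriched in the gene body with depletion at
                  the transcription start/termination sites, near-zero
                  CHG/CHH methylation;
* ``TE_like``   : heterochromatin-like methylation, high in all three
                  contexts;
* ``unmethylated``: no true methylation; apparent methylation arises only
                  from the bisulfite non-conversion rate.

Cytosines are placed with per-context per-strand densities, read depth is
Poisson per site, and each read of an unmethylated cytosine falsely reads
methylated with probability ``ncr`` (non-conversion modelled as
false-methylation only). Identical seeds give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CONTEXTS, write_allc, write_bed, write_gff3

CLASSES = ("gbM", "TE_like", "unmethylated")

N_BODY_WINDOWS = 20


def default_body_profile() -> np.ndarray:
    """Symmetric 20-window multiplier: 0.3 at the gene edges, 1.0 at windows
    9–12, emulating TSS/TTS depletion of gene-body CG methylation."""
    half = np.concatenate([np.linspace(0.3, 1.0, 9), [1.0]])
    return np.concatenate([half, half[::-1]])


def _default_p_meth() -> dict[str, dict[str, float]]:
    return {
        "gbM": {"CG": 0.8, "CHG": 0.01, "CHH": 0.01},
        "TE_like": {"CG": 0.8, "CHG": 0.8, "CHH": 0.8},
        "unmethylated": {"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
    }


def _default_site_density() -> dict[str, float]:
    # per-strand cytosines per bp, roughly angiosperm dinucleotide frequencies
    return {"CG": 0.02, "CHG": 0.02, "CHH": 0.10}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic methylome.

    Defaults describe the reference mixture used throughout the test-bed:
    1000 genes, 70% unmethylated / 20% gbM / 10% TE-like, 20× mean coverage,
    0.5% non-conversion. ``gene_length_range`` is uniform (mean 1.5 kb,
    plant-CDS-like); short genes near 300 bp carry ~12 CG sites, which is
    what makes the ≥10-covered-CG-sites rule coverage-sensitive.
    """

    n_genes: int = 1000
    gene_length_range: tuple[int, int] = (300, 2700)
    intergenic_bp: int = 1000
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {"gbM": 0.2, "TE_like": 0.1, "unmethylated": 0.7}
    )
    p_meth: dict[str, dict[str, float]] = field(default_factory=_default_p_meth)
    gbM_body_profile: np.ndarray = field(default_factory=default_body_profile)
    site_density: dict[str, float] = field(default_factory=_default_site_density)
    mean_coverage: float = 20.0
    ncr: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be ≥ 1")
        lo, hi = self.gene_length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid gene_length_range")
        if self.intergenic_bp < 0:
            raise ValueError("intergenic_bp must be ≥ 0")
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if set(self.class_proportions) - set(CLASSES):
            raise ValueError(f"unknown gene class in {self.class_proportions}")
        for cls, probs in self.p_meth.items():
            for ctx, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"p_meth[{cls}][{ctx}]={p} outside [0,1]")
        prof = np.asarray(self.gbM_body_profile, dtype=float)
        if prof.shape != (N_BODY_WINDOWS,) or (prof < 0).any() or (prof > 1).any():
            raise ValueError("gbM_body_profile must be 20 values in [0,1]")
        if self.mean_coverage < 0:
            raise ValueError("mean_coverage must be ≥ 0")
        if not 0.0 <= self.ncr <= 1.0:
            raise ValueError("ncr must be in [0,1]")


def _body_window(offset: np.ndarray, length: np.ndarray, n_windows: int = N_BODY_WINDOWS) -> np.ndarray:
    """Window index for 0-based offsets within genes of the given lengths.

    Boundaries at round(i·L/n): a site at offset o falls in window w with
    floor(w·L/n + 0.5) ≤ o < floor((w+1)·L/n + 0.5).
    """
    w = np.floor(offset * n_windows / length).astype(np.int64)
    w = np.clip(w, 0, n_windows - 1)
    for _ in range(2):  # rounding shifts boundaries by at most 1
        lower = np.floor(w * length / n_windows + 0.5)
        w = np.where((offset < lower) & (w > 0), w - 1, w)
        upper = np.floor((w + 1) * length / n_windows + 0.5)
        w = np.where((offset >= upper) & (w < n_windows - 1), w + 1, w)
    return w


def simulate_methylome(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate genes, per-cytosine records, and the ground-truth table.

    Returns
    -------
    genes : DataFrame(gene_id, chrom, strand, start, end) — 1-based inclusive
        coding intervals on one synthetic chromosome, alternating strand.
    records : DataFrame(chrom, pos, strand, context, mc, cov) — sorted by
        position then strand; both strands carry sites; intergenic cytosines
        are unmethylated.
    truth : DataFrame(gene_id, true_class, pCG, pCHG, pCHH).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom = "chrS1"

    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    gap = config.intergenic_bp
    starts = gap + 1 + np.concatenate([[0], np.cumsum(lengths[:-1] + gap)])
    ends = starts + lengths - 1
    strands = np.where(np.arange(config.n_genes) % 2 == 0, "+", "-")
    gene_ids = np.array([f"g{i + 1:05d}" for i in range(config.n_genes)])
    genes = pd.DataFrame(
        {"gene_id": gene_ids, "chrom": chrom, "strand": strands,
         "start": starts, "end": ends}
    )

    classes = rng.choice(
        list(config.class_proportions), size=config.n_genes,
        p=list(config.class_proportions.values()),
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_class": classes,
            **{
                f"p{ctx}": [config.p_meth[c][ctx] for c in classes]
                for ctx in CONTEXTS
            },
        }
    )

    genome_len = int(ends[-1] + gap)
    profile = np.asarray(config.gbM_body_profile, dtype=float)

    frames = []
    for ctx in CONTEXTS:
        for strand in ("+", "-"):
            n_sites = rng.poisson(config.site_density[ctx] * genome_len)
            pos = np.sort(rng.choice(genome_len, size=min(n_sites, genome_len), replace=False)) + 1
            # gene containing each site (genes are sorted, non-overlapping)
            gi = np.searchsorted(starts, pos, side="right") - 1
            in_gene = (gi >= 0) & (pos <= ends[np.clip(gi, 0, None)])
            p_true = np.zeros(pos.size)
            idx = np.flatnonzero(in_gene)
            if idx.size:
                g = gi[idx]
                base = np.array([config.p_meth[c][ctx] for c in classes[g]])
                if ctx == "CG":
                    is_gbm = classes[g] == "gbM"
                    if is_gbm.any():
                        gg = g[is_gbm]
                        off = pos[idx][is_gbm] - starts[gg]
                        win = _body_window(off, lengths[gg])
                        # 5'→3' profile: mirror windows on minus-strand genes
                        win = np.where(strands[gg] == "-", N_BODY_WINDOWS - 1 - win, win)
                        base[is_gbm] *= profile[win]
                p_true[idx] = base
            p_app = p_true + (1.0 - p_true) * config.ncr
            cov = rng.poisson(config.mean_coverage, size=pos.size)
            mc = rng.binomial(cov, p_app)
            frames.append(
                pd.DataFrame(
                    {"chrom": chrom, "pos": pos, "strand": strand,
                     "context": ctx, "mc": mc, "cov": cov}
                )
            )
    records = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["pos", "strand", "context"], kind="mergesort")
        .reset_index(drop=True)
    )
    return genes, records, truth


def write_fixture(
    outdir,
    genes: pd.DataFrame,
    records: pd.DataFrame,
    truth: pd.DataFrame,
    gff3: bool = False,
) -> dict[str, Path]:
    """Write the simulated methylome as allc TSV + BED (+ optional GFF3) +
    ground-truth TSV; files round-trip through the readers in :mod:`.io`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "allc": outdir / "allc.tsv",
        "bed": outdir / "genes.bed",
        "truth": outdir / "truth.tsv",
    }
    write_allc(records, paths["allc"])
    write_bed(genes, paths["bed"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    if gff3:
        paths["gff3"] = outdir / "genes.gff3"
        write_gff3(genes, paths["gff3"])
    return paths
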