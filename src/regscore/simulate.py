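"""Synthetic genomes, peaks, motifs and expression with planted structure.

The generator emulates the statistical situation the diagnostics target:
gene-level TF scores that mix true motif-driven signal with aggregate
chromatin confounders.  Concretely it plants

* a random genome with genes at regular spacing,
* open-chromatin peaks around each TSS whose lengths are log-normal —
  the spread (and with it the length confounding of affinity scores) is
  controlled by the ``length_confounding`` dial,
* consensus motif sites for each TF in a random subset of peaks, giving
  every TF column gene-specific variation,
* per-gene regulatory activity that drives the DNase signal of peaks,
* expression built linearly (on the log scale) from the *computed*
  decay-weighted affinity scores of a sparse causal TF set, plus a
  peak-length confounder term and Gaussian noise.

Because expression is constructed from the scores the pipeline itself
computes, recovery of the causal TFs by the regression is a well-posed
target with a known answer.  Identical seeds give byte-identical output
files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .affinity import AffinityTable, annotate_peaks
from .io import EnergyMatrix, GeneModel, Peak
from .scoring import DecayParams, dnase_scores

__all__ = ["FixtureConfig", "Fixture", "generate_fixture", "plant_motifs"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic study; defaults match the benchmark runs."""

    seed: int = 0
    n_genes: int = 2000
    n_tfs: int = 50
    n_causal: int = 5
    causal_weight: float = 1.0
    #: weight of the aggregate-activity (peak length) term in expression
    confounder_weight: float = 1.0
    #: 0..1 dial scaling the spread of peak lengths, hence how strongly
    #: unnormalised affinity scores correlate with peak length
    length_confounding: float = 0.5
    gene_spacing: int = 10_000
    margin: int = 30_000
    chrom: str = "chr1"
    chrom_length: int | None = None
    peak_density: float = 3.0
    peak_length_median: float = 250.0
    min_motif_width: int = 6
    max_motif_width: int = 12
    plant_prob: float = 0.08
    #: noise sd as a fraction of the sd of the deterministic latent
    noise_sd_ratio: float = 0.5
    window: int = 50_000
    d0: float = 5000.0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_tfs) < 1 or self.n_causal > self.n_tfs:
            raise ValueError("invalid gene/TF counts")
        if not 0 <= self.length_confounding <= 1:
            raise ValueError("length_confounding must be in [0, 1]")

    @property
    def effective_chrom_length(self) -> int:
        needed = 2 * self.margin + self.n_genes * self.gene_spacing
        if self.chrom_length is None:
            return needed
        if self.chrom_length < needed:
            raise ValueError(
                f"chrom_length {self.chrom_length} too small for "
                f"{self.n_genes} genes at spacing {self.gene_spacing}"
            )
        return self.chrom_length

    @property
    def peak_length_sdlog(self) -> float:
        # dial 0 -> nearly uniform lengths, dial 1 -> heavy right tail
        return 0.1 + 0.7 * self.length_confounding


@dataclass
class Fixture:
    """Generated inputs, both on disk and in memory."""

    config: FixtureConfig
    paths: dict[str, Path]
    genes: list[GeneModel]
    dnase_peaks: list[Peak]
    chip_peaks_by_tf: dict[str, list[Peak]]
    psems: list[EnergyMatrix]
    affinities: AffinityTable
    d_matrix: "rio.FeatureMatrix"
    peak_features: pd.DataFrame
    expression: pd.Series
    tf_expression: pd.Series
    #: latent per-gene regulatory activity (drives the DNase signal)
    activity: np.ndarray
    ground_truth: dict


def plant_motifs(
    sequence: str,
    matrix: EnergyMatrix,
    n_sites: int,
    rng: np.random.Generator | None = None,
) -> tuple[str, list[int]]:
    """Embed ``n_sites`` non-overlapping consensus sites into a sequence.

    Returns the modified sequence and the (0-based) site start positions.
    Raises when the sites cannot be placed without overlap.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_sites == 0:
        return sequence, []
    width = matrix.width
    if n_sites * width > len(sequence):
        raise ValueError("sequence too short for the requested sites")
    consensus = np.argmin(matrix.energies, axis=1).astype(np.int8)
    codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    occupied: list[tuple[int, int]] = []
    positions: list[int] = []
    for _ in range(n_sites):
        placed = False
        for _attempt in range(200):
            pos = int(rng.integers(0, len(sequence) - width + 1))
            if all(pos + width <= s or pos >= e for s, e in occupied):
                occupied.append((pos, pos + width))
                positions.append(pos)
                codes[pos : pos + width] = _BASES[consensus]
                placed = True
                break
        if not placed:
            raise ValueError("could not place all sites without overlap")
    return codes.tobytes().decode("ascii"), sorted(positions)


def _write_fasta(path: Path, chrom: str, codes: np.ndarray, width: int = 80) -> None:
    seq = _BASES[codes].tobytes().decode("ascii")
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def _write_gtf(path: Path, genes: list[GeneModel], gene_length: int = 2000) -> None:
    with open(path, "w") as fh:
        for g in genes:
            if g.strand == "+":
                start, end = g.tss, g.tss + gene_length - 1
            else:
                start, end = max(1, g.tss - gene_length + 1), g.tss
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(
                f"{g.chrom}\tregscore\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t"
                f'gene_id "{g.gene_id}";\n'
            )
            fh.write(
                f"{g.chrom}\tregscore\ttranscript\t{start}\t{end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def _random_psems(cfg: FixtureConfig, rng: np.random.Generator) -> list[EnergyMatrix]:
    psems = []
    for t in range(cfg.n_tfs):
        width = int(rng.integers(cfg.min_motif_width, cfg.max_motif_width + 1))
        # mismatch energies ~ U(0.5, 1.5): random sequence then carries a
        # small per-window background affinity, so peak-level affinities
        # grow with peak length as they do for real PSEMs
        energies = rng.uniform(0.5, 1.5, size=(width, 4))
        consensus = rng.integers(0, 4, size=width)
        energies[np.arange(width), consensus] = 0.0
        psems.append(EnergyMatrix(tf_name=f"TF{t:03d}", energies=energies))
    return psems


def generate_fixture(config: FixtureConfig, out_dir: str | Path) -> Fixture:
    """Generate and write the full synthetic input set; see module docs."""
    cfg = config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    chrom_len = cfg.effective_chrom_length

    psems = _random_psems(cfg, rng)
    consensus = {m.tf_name: np.argmin(m.energies, axis=1).astype(np.int8) for m in psems}

    genome = rng.integers(0, 4, size=chrom_len, dtype=np.int8)

    # genes on alternating random strands at regular spacing with jitter
    jitter = rng.integers(-cfg.gene_spacing // 4, cfg.gene_spacing // 4 + 1, size=cfg.n_genes)
    strands = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")
    genes = [
        GeneModel(
            gene_id=f"G{i:05d}",
            chrom=cfg.chrom,
            strand=str(strands[i]),
            tss=int(cfg.margin + i * cfg.gene_spacing + jitter[i]) + 1,
        )
        for i in range(cfg.n_genes)
    ]

    # open-chromatin peaks around each TSS; per-gene regulatory activity
    # drives the DNase signal of its peaks
    activity = rng.lognormal(mean=0.0, sigma=0.75, size=cfg.n_genes)
    half = cfg.window // 2
    intervals: dict[tuple[int, int], float] = {}
    for i, g in enumerate(genes):
        n_p = rng.poisson(cfg.peak_density)
        for _ in range(n_p):
            center = int(rng.integers(g.tss0 - half, g.tss0 + half))
            length = int(
                np.clip(
                    rng.lognormal(np.log(cfg.peak_length_median), cfg.peak_length_sdlog),
                    20,
                    5000,
                )
            )
            start = int(np.clip(center - length // 2, 0, chrom_len - length))
            sig = float(activity[i] * rng.lognormal(0.0, 0.5))
            key = (start, start + length)
            if key not in intervals:
                intervals[key] = sig
    dnase_peaks = [
        Peak(cfg.chrom, s, e, score=0.0, signal=intervals[(s, e)], name=f"dhs{j}")
        for j, (s, e) in enumerate(sorted(intervals))
    ]
    if not dnase_peaks:
        raise ValueError("no peaks generated; increase peak_density or n_genes")

    # plant consensus sites: each (peak, TF) pair independently with
    # plant_prob, 1 + Poisson(0.3) sites, non-overlapping within the peak
    planted: dict[str, set[int]] = {m.tf_name: set() for m in psems}
    select = rng.random((len(dnase_peaks), cfg.n_tfs)) < cfg.plant_prob
    for j, p in enumerate(dnase_peaks):
        occupied: list[tuple[int, int]] = []
        for t in np.flatnonzero(select[j]):
            m = psems[t]
            if p.length < m.width:
                continue
            n_sites = 1 + rng.poisson(0.3)
            placed_any = False
            for _ in range(n_sites):
                for _attempt in range(50):
                    pos = int(rng.integers(p.start, p.end - m.width + 1))
                    if all(pos + m.width <= s or pos >= e for s, e in occupied):
                        occupied.append((pos, pos + m.width))
                        genome[pos : pos + m.width] = consensus[m.tf_name]
                        placed_any = True
                        break
            if placed_any:
                planted[m.tf_name].add(j)

    # ChIP peaks: a TF "binds" where its sites were planted, plus a small
    # false-positive rate over the remaining DHSs
    chip_peaks_by_tf: dict[str, list[Peak]] = {}
    for m in psems:
        rows = []
        for j, p in enumerate(dnase_peaks):
            bound = j in planted[m.tf_name]
            if not bound and rng.random() >= 0.02:
                continue
            score = float((80.0 if bound else 30.0) * rng.lognormal(0.0, 0.3))
            rows.append(Peak(p.chrom, p.start, p.end, score=score, signal=0.0, name=f"{m.tf_name}_{j}"))
        chip_peaks_by_tf[m.tf_name] = rows

    # score the peaks with the real machinery
    seq = _BASES[genome].tobytes().decode("ascii")
    affinities = annotate_peaks(dnase_peaks, {cfg.chrom: seq}, psems)
    params = DecayParams(d0=cfg.d0, window=cfg.window)
    d_matrix = dnase_scores(genes, dnase_peaks, affinities, params, "D")
    dpfs = dnase_scores(genes, dnase_peaks, None, params, "DPFS")
    peak_features = dpfs.values

    # expression: sparse causal combination of computed (log) D scores
    # plus a peak-length confounder term and Gaussian noise
    causal_idx = rng.choice(cfg.n_tfs, size=cfg.n_causal, replace=False)
    causal_tfs = [psems[t].tf_name for t in sorted(causal_idx)]

    def zscore(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    latent = np.zeros(cfg.n_genes)
    for tf in causal_tfs:
        latent += cfg.causal_weight * zscore(np.log2(1.0 + d_matrix.values[tf].to_numpy()))
    latent += cfg.confounder_weight * zscore(
        np.log2(1.0 + peak_features["Peak_Length"].to_numpy())
    )
    det_sd = latent.std()
    noise_sd = cfg.noise_sd_ratio * (det_sd if det_sd > 0 else 1.0)
    latent = latent + rng.normal(0.0, noise_sd, size=cfg.n_genes)
    log_expr = 5.0 + 1.5 * zscore(latent)
    expression = pd.Series(
        np.maximum(np.exp2(log_expr) - 1.0, 0.0),
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
        name="expression",
    )

    # TF expression (TPM) for the expressed-regulator check and the gold
    # standard: causal TFs are always expressed, others with prob 0.6
    expressed = rng.random(cfg.n_tfs) < 0.6
    tf_tpm = np.where(
        expressed, rng.lognormal(np.log(50.0), 1.0, cfg.n_tfs), rng.lognormal(0.0, 0.8, cfg.n_tfs)
    )
    for t in causal_idx:
        tf_tpm[t] = max(tf_tpm[t], float(rng.lognormal(np.log(100.0), 0.5)))
    tf_expression = pd.Series(
        tf_tpm, index=pd.Index([m.tf_name for m in psems], name="gene_id"), name="expression"
    )

    # ----- write everything ------------------------------------------------
    paths: dict[str, Path] = {}
    paths["genome"] = out / "genome.fa"
    _write_fasta(paths["genome"], cfg.chrom, genome)
    paths["genes"] = out / "genes.gtf"
    _write_gtf(paths["genes"], genes)
    paths["dnase_peaks"] = out / "dnase.narrowPeak"
    rio.write_peaks(dnase_peaks, paths["dnase_peaks"], format="narrowPeak")
    chip_dir = out / "chip"
    chip_dir.mkdir(exist_ok=True)
    manifest_rows = []
    for tf, pk in chip_peaks_by_tf.items():
        p = chip_dir / f"{tf}.narrowPeak"
        rio.write_peaks(pk, p, format="narrowPeak")
        manifest_rows.append(f"{tf}\tchip/{p.name}")  # paths relative to out_dir
    paths["chip_manifest"] = out / "chip_manifest.tsv"
    paths["chip_manifest"].write_text("\n".join(manifest_rows) + "\n")
    paths["psem"] = out / "motifs.psem"
    rio.write_psem(psems, paths["psem"])
    paths["expression"] = out / "expression.tsv"
    rio.write_expression(expression, paths["expression"])
    paths["tf_expression"] = out / "tf_expression.tsv"
    rio.write_expression(tf_expression, paths["tf_expression"])

    ground_truth = {
        "seed": cfg.seed,
        "n_genes": cfg.n_genes,
        "n_tfs": cfg.n_tfs,
        "causal_tfs": causal_tfs,
        "causal_weight": cfg.causal_weight,
        "confounder_weight": cfg.confounder_weight,
        "length_confounding": cfg.length_confounding,
        "noise_sd_ratio": cfg.noise_sd_ratio,
        "noise_sd": float(noise_sd),
    }
    paths["ground_truth"] = out / "ground_truth.json"
    paths["ground_truth"].write_text(json.dumps(ground_truth, indent=2, sort_keys=True) + "\n")

    return Fixture(
        config=cfg,
        paths=paths,
        genes=genes,
        dnase_peaks=dnase_peaks,
        chip_peaks_by_tf=chip_peaks_by_tf,
        psems=psems,
        affinities=affinities,
        d_matrix=d_matrix,
        peak_features=peak_features,
        expression=expression,
        tf_expression=tf_expression,
        activity=activity,
        ground_truth=ground_truth,
    )
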