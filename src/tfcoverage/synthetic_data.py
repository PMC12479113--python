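"""Synthetic ChIP-seq "world" generator with planted ground truth.

Emulates the statistical structure the coverage audit assumes, end to end:

* experiment metadata whose TF/cell-type assignment follows preferential
  attachment (``P(tf) ∝ (count + 1)^attachment_strength``), reproducing the
  rich-get-richer skew of real compendia with a single knob;
* a gene x cell-line expression matrix drawn from a two-component log-normal
  mixture (heavy-tailed like nTPM values), with the true expressed pairs
  recorded;
* TSS annotations on a toy genome, and per-experiment peak files enriched in
  the promoter windows of genes expressed in the experiment's cell type;
* GWAS-style SNPs, knockout DEG counts with a marker shift, TF-marker
  annotations, and a balanced cell-type -> class ontology map;
* optionally, *planted hidden gems*: expressed, unmeasured, marker-flagged
  pairs pushed over the DEG threshold — with every competing pair capped at
  the threshold, so the downstream filter can be validated exactly.

Everything is deterministic given ``WorldConfig.seed``: each artifact draws
from its own named substream, so regenerating any one table is byte-stable
regardless of the others.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io_formats
from .coverage import make_promoter_windows

_STREAMS = {"metadata": 1, "expression": 2, "tss": 3, "peaks": 4,
            "snps": 5, "deg": 6, "pubs": 7, "tfpool": 8}


class PlantingError(RuntimeError):
    """Raised when no expressed-but-unmeasured pair exists to plant a gem."""


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the synthetic world (defaults = the study conditions).

    Sizes are desk-scale but structured like the real inputs: tens of TFs and
    cell lines, hundreds of experiments spread over two decades, a megabase
    toy genome.  ``attachment_strength`` 1.0 gives a Polya-urn level of skew;
    the log-normal mixture (mu_low 0, mu_high 4, sigma 0.8) separates the
    expressed component by 5 sigma, about what a clean bimodal nTPM profile
    looks like.
    """

    n_tfs: int = 60
    n_cell_types: int = 30
    n_classes: int = 6
    n_experiments: int = 600
    years: tuple[int, int] = (2005, 2023)
    attachment_strength: float = 1.0
    pi_expressed: float = 0.3
    mu_low: float = 0.0
    mu_high: float = 4.0
    sigma: float = 0.8
    genome: tuple[tuple[str, int], ...] = (("chr1", 1_000_000),
                                           ("chr2", 700_000))
    n_tss: int = 300            # genes with a TSS; the first n_tfs are the TFs
    flank: int = 500            # promoter half-width used for peak enrichment
    peak_width: int = 200
    peaks_per_experiment: int = 50
    tss_enrichment: float = 0.5
    tf_specific_peaks: bool = False
    n_snps: int = 400
    deg_meanlog: float = 6.0
    deg_sdlog: float = 1.0
    marker_shift: float = 1.5   # added to meanlog for marker TFs (delta > 0)
    marker_fraction: float = 0.25
    deg_threshold: int = 1000
    n_planted_gems: int = 2
    seed: int = 0

    def __post_init__(self):
        for name in ("n_tfs", "n_cell_types", "n_classes", "n_experiments",
                     "n_tss", "n_snps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.pi_expressed <= 1.0:
            raise ValueError("pi_expressed must be in [0, 1]")
        if not self.mu_low < self.mu_high:
            raise ValueError("mu_low must be < mu_high")
        if not 0.0 <= self.tss_enrichment <= 1.0:
            raise ValueError("tss_enrichment must be in [0, 1]")
        if self.attachment_strength < 0:
            raise ValueError("attachment_strength must be >= 0")
        if self.n_tss < self.n_tfs:
            raise ValueError("n_tss must be >= n_tfs (TFs are genes)")
        if any(length <= self.peak_width for _, length in self.genome):
            raise ValueError("every chromosome must exceed peak_width")
        if self.years[0] > self.years[1]:
            raise ValueError("years must be an inclusive (lo, hi) range")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["years"] = list(self.years)
        d["genome"] = [list(g) for g in self.genome]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "WorldConfig":
        d = dict(d)
        if "years" in d:
            d["years"] = tuple(d["years"])
        if "genome" in d:
            d["genome"] = tuple((str(c), int(n)) for c, n in d["genome"])
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must rediscover."""

    true_expressed: frozenset          # (gene, cell_line) pairs, all genes
    expressed_tf_class: frozenset      # (tf, class) pairs, truth-aggregated
    planted_gems: frozenset            # (tf, class) pairs
    marker_tfs: frozenset


@dataclass
class SyntheticWorld:
    config: WorldConfig
    metadata: pd.DataFrame
    expression: pd.DataFrame
    tss: pd.DataFrame
    snps: pd.DataFrame
    deg: pd.DataFrame
    markers: pd.DataFrame
    class_map: pd.Series
    publications: pd.DataFrame
    peaks: dict = field(default_factory=dict)
    truth: GroundTruth | None = None

    @property
    def tfs(self) -> list[str]:
        return tf_names(self.config)


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, _STREAMS[stream], extra]))


def tf_names(config: WorldConfig) -> list[str]:
    return [f"TF{i:03d}" for i in range(1, config.n_tfs + 1)]


def gene_names(config: WorldConfig) -> list[str]:
    extra = [f"G{i:04d}" for i in range(1, config.n_tss - config.n_tfs + 1)]
    return tf_names(config) + extra


def cell_type_names(config: WorldConfig) -> list[str]:
    return [f"CL-{i:03d}" for i in range(1, config.n_cell_types + 1)]


def class_names(config: WorldConfig) -> list[str]:
    return [f"CLASS{i:02d}" for i in range(1, config.n_classes + 1)]


def class_map(config: WorldConfig) -> pd.Series:
    """Balanced cell-type -> class partition (cell i -> class i mod k)."""
    cells = cell_type_names(config)
    classes = class_names(config)
    return pd.Series([classes[i % config.n_classes]
                      for i in range(len(cells))],
                     index=cells, name="cell_type_class")


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def _preferential_choice(rng, n_entities: int, n_draws: int,
                         strength: float) -> np.ndarray:
    counts = np.zeros(n_entities)
    out = np.empty(n_draws, dtype=int)
    for i in range(n_draws):
        w = (counts + 1.0) ** strength
        j = rng.choice(n_entities, p=w / w.sum())
        counts[j] += 1
        out[i] = j
    return out


def generate_metadata(config: WorldConfig) -> pd.DataFrame:
    """Experiment metadata under preferential attachment.

    Each experiment picks its TF and its cell type with probability
    proportional to ``(current count + 1)^attachment_strength``; deposit
    dates are uniform over the configured year range.
    """
    rng = _rng(config.seed, "metadata")
    tfs = tf_names(config)
    cells = cell_type_names(config)
    cmap = class_map(config)
    tf_idx = _preferential_choice(rng, config.n_tfs, config.n_experiments,
                                  config.attachment_strength)
    cell_idx = _preferential_choice(rng, config.n_cell_types,
                                    config.n_experiments,
                                    config.attachment_strength)
    lo, hi = config.years
    year = rng.integers(lo, hi + 1, size=config.n_experiments)
    doy = rng.integers(0, 365, size=config.n_experiments)
    dates = (pd.to_datetime([f"{y}-01-01" for y in year])
             + pd.to_timedelta(doy, unit="D"))
    # clamp the rare Dec-31-overflow back into the deposit year
    dates = pd.to_datetime(
        np.where(dates.year == year, dates, pd.to_datetime(
            [f"{y}-12-31" for y in year])))
    cell_types = [cells[j] for j in cell_idx]
    return pd.DataFrame({
        "experiment_id": [f"EXP{i:06d}" for i in range(1, config.n_experiments + 1)],
        "antigen": [tfs[j] for j in tf_idx],
        "cell_type": cell_types,
        "cell_type_class": [cmap[c] for c in cell_types],
        "deposit_date": dates,
    })


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(config: WorldConfig,
                        ) -> tuple[pd.DataFrame, frozenset]:
    """Gene x cell-line matrix from the expressed/not-expressed mixture.

    Membership of each (gene, line) pair in the expressed component is
    Bernoulli(``pi_expressed``); values are ``exp(N(mu, sigma))`` with mu the
    component mean.  Returns the matrix and the true expressed pair set.
    """
    rng = _rng(config.seed, "expression")
    genes = gene_names(config)
    cells = cell_type_names(config)
    member = rng.random((len(genes), len(cells))) < config.pi_expressed
    mu = np.where(member, config.mu_high, config.mu_low)
    vals = np.exp(rng.normal(mu, config.sigma))
    expr = pd.DataFrame(vals, index=pd.Index(genes, name="gene"),
                        columns=pd.Index(cells, name="cell_line"))
    gi, ci = np.nonzero(member)
    truth = frozenset((genes[i], cells[j]) for i, j in zip(gi, ci))
    return expr, truth


def generate_tss(config: WorldConfig) -> pd.DataFrame:
    """One TSS per gene, uniform over the toy genome (0-based positions)."""
    rng = _rng(config.seed, "tss")
    chroms = [c for c, _ in config.genome]
    lengths = np.array([n for _, n in config.genome], dtype=float)
    genes = gene_names(config)
    ci = rng.choice(len(chroms), size=len(genes), p=lengths / lengths.sum())
    pos = np.array([rng.integers(0, config.genome[c][1]) for c in ci])
    return pd.DataFrame({"chrom": [chroms[c] for c in ci],
                         "start": pos, "end": pos + 1, "gene": genes})


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def tf_peak_pool(config: WorldConfig, tf_index: int) -> pd.DataFrame:
    """Fixed binding repertoire of one TF (tf_specific_peaks mode).

    Derived from the world seed and the TF index only, so the repertoire is
    identical across worlds sharing a seed — coverage then depends on *which*
    TFs were measured, not on how often.
    """
    rng = _rng(config.seed, "tfpool", tf_index)
    chroms = [c for c, _ in config.genome]
    lengths = np.array([n for _, n in config.genome], dtype=float)
    ci = rng.choice(len(chroms), size=config.peaks_per_experiment,
                    p=lengths / lengths.sum())
    starts = np.array([rng.integers(0, config.genome[c][1] - config.peak_width)
                       for c in ci])
    return pd.DataFrame({"chrom": [chroms[c] for c in ci], "start": starts,
                         "end": starts + config.peak_width})


def generate_peaks(config: WorldConfig, metadata: pd.DataFrame,
                   tss: pd.DataFrame, true_expressed: frozenset,
                   ) -> dict[str, pd.DataFrame]:
    """Per-experiment peak tables.

    Default mode: a ``tss_enrichment`` fraction of each experiment's peaks is
    centred inside promoter windows of genes truly expressed in the
    experiment's cell type; the rest land uniformly on the genome.  In
    ``tf_specific_peaks`` mode every experiment re-emits its TF's fixed
    repertoire instead (replicates add no new coverage).
    """
    rng = _rng(config.seed, "peaks")
    chroms = [c for c, _ in config.genome]
    lengths = np.array([n for _, n in config.genome], dtype=float)
    chrom_len = dict(config.genome)
    width = config.peak_width
    tfs = tf_names(config)
    tf_index = {t: i for i, t in enumerate(tfs)}

    if config.tf_specific_peaks:
        pools = {t: tf_peak_pool(config, tf_index[t]) for t in
                 sorted(set(metadata["antigen"]))}
        return {r.experiment_id: pools[r.antigen].copy()
                for r in metadata.itertuples(index=False)}

    tss_by_gene = tss.set_index("gene")
    expressed_by_cell: dict[str, list[str]] = {}
    for g, c in true_expressed:
        expressed_by_cell.setdefault(c, []).append(g)
    for c in expressed_by_cell:
        expressed_by_cell[c].sort()

    out: dict[str, pd.DataFrame] = {}
    n_total = config.peaks_per_experiment
    n_enr_target = int(round(config.tss_enrichment * n_total))
    for r in metadata.itertuples(index=False):
        genes = expressed_by_cell.get(r.cell_type, [])
        n_enr = n_enr_target if genes else 0
        rows_chrom: list[str] = []
        rows_start: list[int] = []
        for _ in range(n_enr):
            g = genes[rng.integers(0, len(genes))]
            t = tss_by_gene.loc[g]
            p0 = int(t["start"])
            L = chrom_len[t["chrom"]]
            center = p0 + int(rng.integers(-config.flank, config.flank + 1))
            center = min(max(center, 0), L - 1)
            start = min(max(center - width // 2, 0), L - width)
            rows_chrom.append(t["chrom"])
            rows_start.append(start)
        for _ in range(n_total - n_enr):
            c = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
            rows_chrom.append(chroms[c])
            rows_start.append(int(rng.integers(0, chrom_len[chroms[c]] - width + 1)))
        starts = np.array(rows_start, dtype=int)
        out[r.experiment_id] = pd.DataFrame(
            {"chrom": rows_chrom, "start": starts, "end": starts + width})
    return out


def generate_snps(config: WorldConfig) -> pd.DataFrame:
    """GWAS-style SNP table: unique rsIDs, 1-based positions."""
    rng = _rng(config.seed, "snps")
    chroms = [c for c, _ in config.genome]
    lengths = np.array([n for _, n in config.genome], dtype=float)
    ci = rng.choice(len(chroms), size=config.n_snps,
                    p=lengths / lengths.sum())
    pos = np.array([rng.integers(1, config.genome[c][1] + 1) for c in ci])
    df = pd.DataFrame({"rsid": [f"rs{i:06d}" for i in range(1, config.n_snps + 1)],
                       "chrom": [chroms[c] for c in ci], "pos": pos})
    df["start"] = df["pos"] - 1
    df["end"] = df["pos"]
    return df


# ---------------------------------------------------------------------------
# DEG counts, markers, gem planting
# ---------------------------------------------------------------------------

def _expressed_tf_class(config: WorldConfig,
                        true_expressed: frozenset) -> frozenset:
    cmap = class_map(config)
    tfs = set(tf_names(config))
    return frozenset({(g, cmap[c]) for g, c in true_expressed if g in tfs})


def generate_deg_and_markers(config: WorldConfig, metadata: pd.DataFrame,
                             true_expressed: frozenset,
                             ) -> tuple[pd.DataFrame, pd.DataFrame,
                                        frozenset, frozenset]:
    """Knockout DEG counts, marker annotations, and planted gems.

    DEG counts are log-normal; marker TFs get ``marker_shift`` added to the
    meanlog (delta > 0 makes the marker-vs-nonmarker Wilcoxon comparison
    well-powered).  When ``n_planted_gems > 0``, that many expressed,
    unmeasured (TF, class) pairs are planted as gems (forced marker, DEG
    count pushed above the threshold) and every competing qualifying pair is
    capped at the threshold so the filter's output is exactly the planted
    set.  Returns (deg, markers, planted_gems, marker_tfs).
    """
    rng = _rng(config.seed, "deg")
    tfs = tf_names(config)
    classes = class_names(config)
    marker_mask = rng.random(config.n_tfs) < config.marker_fraction
    marker_tfs = {t for t, m in zip(tfs, marker_mask) if m}

    rows: list[tuple[str, str, int]] = []
    for t in tfs:
        k = int(rng.integers(1, min(4, config.n_classes + 1)))
        chosen = rng.choice(config.n_classes, size=k, replace=False)
        for ci in sorted(chosen):
            shift = config.marker_shift if t in marker_tfs else 0.0
            n_deg = int(round(rng.lognormal(config.deg_meanlog + shift,
                                            config.deg_sdlog)))
            rows.append((t, classes[ci], n_deg))
    deg = pd.DataFrame(rows, columns=["tf", "sample", "n_deg"])

    expressed_tc = _expressed_tf_class(config, true_expressed)
    measured_tc = set(zip(metadata["antigen"], metadata["cell_type_class"]))
    planted: frozenset = frozenset()
    if config.n_planted_gems > 0:
        candidates = sorted(expressed_tc - measured_tc)
        if len(candidates) < config.n_planted_gems:
            raise PlantingError(
                f"cannot plant {config.n_planted_gems} gems: only "
                f"{len(candidates)} expressed-but-unmeasured (TF, class) "
                f"pairs exist")
        pick = rng.choice(len(candidates), size=config.n_planted_gems,
                          replace=False)
        planted = frozenset(candidates[i] for i in sorted(pick))
        for t, c in sorted(planted):
            marker_tfs.add(t)
            n_deg = int(config.deg_threshold * rng.uniform(1.5, 3.0))
            mask = (deg["tf"] == t) & (deg["sample"] == c)
            if mask.any():
                deg.loc[mask, "n_deg"] = n_deg
            else:
                deg.loc[len(deg)] = (t, c, n_deg)
        # exclusivity: cap every other qualifying pair at the threshold
        # (strict > excludes it), so planted gems are the exact answer
        eligible = np.array(
            [((t, c) in expressed_tc and (t, c) not in measured_tc
              and (t, c) not in planted)
             for t, c in zip(deg["tf"], deg["sample"])])
        qualifies = (deg["n_deg"] > config.deg_threshold) \
            & deg["tf"].isin(marker_tfs) & eligible
        deg.loc[qualifies, "n_deg"] = config.deg_threshold

    deg = deg.sort_values(["tf", "sample"], kind="mergesort",
                          ignore_index=True)
    markers = pd.DataFrame({"tf": sorted(marker_tfs)})
    markers["source"] = "synthetic"
    return deg, markers, planted, frozenset(marker_tfs)


def generate_publications(config: WorldConfig,
                          metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-TF publication counts, noisily proportional to experiment counts
    (research attention and measurement effort go hand in hand)."""
    rng = _rng(config.seed, "pubs")
    tfs = tf_names(config)
    counts = metadata.groupby("antigen").size().reindex(tfs, fill_value=0)
    lam = 2.0 + 2.0 * counts.to_numpy() * np.exp(rng.normal(0.0, 0.6, len(tfs)))
    return pd.DataFrame({"tf": tfs, "n_publications": rng.poisson(lam)})


# ---------------------------------------------------------------------------
# whole world
# ---------------------------------------------------------------------------

def generate_world(config: WorldConfig | None = None, **overrides,
                   ) -> SyntheticWorld:
    """Generate every table plus ground truth for one world."""
    if config is None:
        config = WorldConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    metadata = generate_metadata(config)
    expression, true_expressed = generate_expression(config)
    tss = generate_tss(config)
    peaks = generate_peaks(config, metadata, tss, true_expressed)
    snps = generate_snps(config)
    deg, markers, planted, marker_tfs = generate_deg_and_markers(
        config, metadata, true_expressed)
    publications = generate_publications(config, metadata)
    truth = GroundTruth(
        true_expressed=true_expressed,
        expressed_tf_class=_expressed_tf_class(config, true_expressed),
        planted_gems=planted,
        marker_tfs=marker_tfs)
    return SyntheticWorld(config=config, metadata=metadata,
                          expression=expression, tss=tss, snps=snps,
                          deg=deg, markers=markers,
                          class_map=class_map(config),
                          publications=publications, peaks=peaks,
                          truth=truth)


def write_world(world: SyntheticWorld, outdir) -> dict:
    """Write the world in exactly the formats the readers consume.

    Returns the manifest (also saved as ``manifest.yaml``), which records the
    config (including the seed) and every file path, plus the ground-truth
    tables under ``truth/``.
    """
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    io_formats.write_experiment_table(world.metadata, outdir / "metadata.tsv")
    io_formats.write_expression_matrix(world.expression,
                                       outdir / "expression.tsv")
    io_formats.write_bed(world.tss, outdir / "tss.bed")
    io_formats.write_snp_table(world.snps, outdir / "snps.tsv")
    io_formats.write_deg_table(world.deg, outdir / "deg.tsv")
    world.markers.to_csv(outdir / "markers.tsv", sep="\t", index=False)
    io_formats.write_class_map(world.class_map, outdir / "class_map.tsv")
    world.publications.to_csv(outdir / "publications.tsv", sep="\t",
                              index=False)
    (outdir / "tfs.txt").write_text("\n".join(tf_names(world.config)) + "\n")
    for exp_id in sorted(world.peaks):
        io_formats.write_bed(world.peaks[exp_id],
                             outdir / "peaks" / f"{exp_id}.bed")
    truth = world.truth
    pd.DataFrame(sorted(truth.true_expressed),
                 columns=["gene", "cell_line"]).to_csv(
        outdir / "truth" / "true_expressed.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(truth.expressed_tf_class),
                 columns=["tf", "cell_type_class"]).to_csv(
        outdir / "truth" / "expressed_tf_class.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(truth.planted_gems),
                 columns=["tf", "cell_type_class"]).to_csv(
        outdir / "truth" / "planted_gems.tsv", sep="\t", index=False)
    manifest = {
        "config": world.config.to_dict(),
        "files": {
            "metadata": "metadata.tsv", "expression": "expression.tsv",
            "tss": "tss.bed", "snps": "snps.tsv", "deg": "deg.tsv",
            "markers": "markers.tsv", "class_map": "class_map.tsv",
            "publications": "publications.tsv", "tfs": "tfs.txt",
            "peaks_dir": "peaks",
            "truth": {"true_expressed": "truth/true_expressed.tsv",
                      "expressed_tf_class": "truth/expressed_tf_class.tsv",
                      "planted_gems": "truth/planted_gems.tsv"},
        },
    }
    io_formats.dump_config(manifest, outdir / "manifest.yaml")
    return manifest


def load_world(indir) -> SyntheticWorld:
    """Reload a written world (ground truth included) through the readers."""
    indir = Path(indir)
    manifest = io_formats.load_config(indir / "manifest.yaml")
    config = WorldConfig.from_dict(manifest["config"])
    metadata, _ = io_formats.read_experiment_table(indir / "metadata.tsv")
    expression = io_formats.read_expression_matrix(indir / "expression.tsv")
    tss_bed = io_formats.read_bed(indir / "tss.bed")
    tss = tss_bed.rename(columns={"name": "gene"})
    snps, _ = io_formats.read_snp_table(indir / "snps.tsv")
    deg = io_formats.read_deg_table(indir / "deg.tsv")
    markers = io_formats.read_marker_table(indir / "markers.tsv")
    cmap = io_formats.read_class_map(indir / "class_map.tsv")
    publications = pd.read_csv(indir / "publications.tsv", sep="\t")
    peaks = {p.stem: io_formats.read_bed(p)
             for p in sorted((indir / "peaks").glob("*.bed"))}
    te = pd.read_csv(indir / "truth" / "true_expressed.tsv", sep="\t")
    etc = pd.read_csv(indir / "truth" / "expressed_tf_class.tsv", sep="\t")
    gems = pd.read_csv(indir / "truth" / "planted_gems.tsv", sep="\t")
    truth = GroundTruth(
        true_expressed=frozenset(zip(te["gene"], te["cell_line"])),
        expressed_tf_class=frozenset(zip(etc["tf"], etc["cell_type_class"])),
        planted_gems=frozenset(zip(gems["tf"], gems["cell_type_class"])),
        marker_tfs=frozenset(markers["tf"]))
    return SyntheticWorld(config=config, metadata=metadata,
                          expression=expression, tss=tss, snps=snps,
                          deg=deg, markers=markers, class_map=cmap,
                          publications=publications, peaks=peaks,
                          truth=truth)
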