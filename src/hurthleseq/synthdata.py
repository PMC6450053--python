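"""Synthetic FNA cohort generator: counts, variant calls and truth labels.

The generator emulates the statistical structure the classifier stack
assumes, at desk scale and with a ground-truth ledger, so every stage is
testable without any sequencing data:

* four cytology classes (H+N+, H+N-, H-N+, H-N-) with default sizes matching
  a ~300-sample development cohort: 199 Hurthle-positive vs 119 negative,
  and a neoplasm-labelled subset of 98 (71 N+ / 27 N-);
* negative-binomial counts with log-normal baseline means and expression
  programs driven by sample-level latent activities (class indicator plus
  Gaussian noise) times per-gene loadings -- the 13 mitochondrial
  protein-coding genes are elevated in H+ samples, a neoplasm program marks
  H+N+ samples, and a malignancy program marks histologically malignant
  samples;
* per-chromosome variant calls whose VAFs are Beta-distributed around 0.5,
  with a planted fraction of extreme VAFs (allelic imbalance) on a subset of
  chromosomes in H+N+ samples, plus a sprinkling of homozygous VAF=1 calls
  to exercise pre-filtering; read depths are Poisson so realized VAFs carry
  binomial sampling noise;
* histology benign/malignant labels derived from the neoplasm class with
  configurable noise, and LOH planting that is enriched in -- but not
  exclusive to -- malignant neoplasms.

Latent program activities (rather than fixed independent per-gene shifts)
keep many-gene aggregation honest: the separability of each program is
bounded by its activity noise, the way correlated real programs behave,
while group-mean log2 fold-changes still equal the per-gene loadings.
Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import MT_PROTEIN_CODING, ExpressionMatrix, read_annotation, read_counts
from .variant_loh import (
    AUTOSOMES,
    CANONICAL_CHROMOSOMES,
    VariantCall,
    VariantSet,
    read_variants_vcf,
)

logger = logging.getLogger(__name__)

CYTO_CLASSES = ("H+N+", "H+N-", "H-N+", "H-N-")


@dataclass(frozen=True)
class ProgramSpec:
    """One planted expression program: gene count, effect size, sample-level noise.

    ``log2fc`` is the maximum per-gene group-mean log2 fold-change; each
    program gene's loading is log2fc scaled by a uniform draw from
    ``loading_range`` with a random sign (two-sided program).
    ``activity_sd`` is the within-class standard deviation of the latent
    activity whose between-class mean difference is 1; it bounds how
    separable the program can ever make the two classes.
    """

    n_genes: int
    log2fc: float
    activity_sd: float
    loading_range: tuple[float, float] = (0.75, 1.0)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort. Defaults are the development-cohort conditions."""

    # cytology class sizes: 318 total, 199 H+ / 119 H-
    n_hpos_npos: int = 71
    n_hpos_nneg: int = 128
    n_hneg_npos: int = 40
    n_hneg_nneg: int = 79
    #: H+N- samples carrying a confident neoplasm-negative label; together
    #: with all H+N+ samples they form the 98-sample NI training subset.
    n_ni_labelled_nneg: int = 27
    # expression
    n_genes: int = 2000
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 0.15
    library_log_sd: float = 0.25
    mito_log2fc: float = 3.0
    mito_baseline_scale: float = 10.0
    h_program: ProgramSpec = ProgramSpec(n_genes=60, log2fc=2.0, activity_sd=0.25)
    #: deliberately weak: cytological neoplasm status has only an indirect
    #: transcriptional signature, which is why LOH features are needed at all
    n_program: ProgramSpec = ProgramSpec(n_genes=15, log2fc=1.0, activity_sd=1.0)
    bm_program: ProgramSpec = ProgramSpec(n_genes=30, log2fc=1.0, activity_sd=0.5)
    # histology labels (simulation conventions: neoplasm != malignant)
    p_malignant_npos: float = 0.55
    p_malignant_nneg: float = 0.05
    # variants / LOH
    loh_chromosomes: tuple[str, ...] = ("1", "2", "3", "8", "9", "13")
    #: multi-chromosome LOH is characteristic of Hurthle neoplasms, enriched
    #: in (but not exclusive to) the malignant ones
    p_loh_malignant: float = 0.95
    p_loh_benign: float = 0.55
    loh_fraction: float = 0.6
    variants_per_chromosome: int = 80
    baseline_vaf_beta: tuple[float, float] = (6.0, 6.0)
    p_homozygous: float = 0.08
    read_depth_mean: float = 40.0
    seed: int = 0

    def class_sizes(self) -> dict[str, int]:
        return {
            "H+N+": self.n_hpos_npos,
            "H+N-": self.n_hpos_nneg,
            "H-N+": self.n_hneg_npos,
            "H-N-": self.n_hneg_nneg,
        }


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground-truth ledger of every planted signal."""

    expression: ExpressionMatrix
    variant_tables: dict[str, pd.DataFrame]
    labels: pd.DataFrame
    ledger: dict
    spec: CohortSpec

    def variant_set(self, sample_id: str) -> VariantSet:
        t = self.variant_tables[sample_id]
        calls = [
            VariantCall(chromosome=c, position=int(p), vaf=float(v))
            for c, p, v in zip(t["chromosome"], t["position"], t["vaf"])
        ]
        return VariantSet(sample_id=sample_id, variants=calls)

    def variant_sets(self) -> dict[str, VariantSet]:
        return {sid: self.variant_set(sid) for sid in self.variant_tables}


def _variant_table(
    rng: np.random.Generator, spec: CohortSpec, has_loh: bool
) -> pd.DataFrame:
    """Variant calls for one sample across all canonical chromosomes."""
    a, b = spec.baseline_vaf_beta
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    true_vafs: list[np.ndarray] = []
    k = spec.variants_per_chromosome
    for chrom in CANONICAL_CHROMOSOMES:
        pos = np.sort(rng.integers(1, 200_000_000, size=k))
        vaf = rng.beta(a, b, size=k)
        homo = rng.random(k) < spec.p_homozygous
        vaf[homo] = 1.0
        if has_loh and chrom in spec.loh_chromosomes:
            hit = (~homo) & (rng.random(k) < spec.loh_fraction)
            n_hit = int(hit.sum())
            lo = rng.uniform(0.02, 0.18, size=n_hit)
            hi = rng.uniform(0.82, 0.98, size=n_hit)
            vaf[hit] = np.where(rng.random(n_hit) < 0.5, lo, hi)
        chroms.extend([chrom] * k)
        positions.append(pos)
        true_vafs.append(vaf)
    pos = np.concatenate(positions)
    tv = np.concatenate(true_vafs)
    depth = np.maximum(rng.poisson(spec.read_depth_mean, size=len(tv)), 1)
    alt = rng.binomial(depth, tv)
    return pd.DataFrame(
        {
            "chromosome": chroms,
            "position": pos,
            "ref_depth": depth - alt,
            "alt_depth": alt,
            "vaf": alt / depth,
        }
    )


def generate_variants(
    sample_class: str,
    spec: CohortSpec,
    has_loh: bool | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str = "sample",
) -> VariantSet:
    """Variant calls for one sample of the given cytology class.

    LOH is planted only for H+N+ samples (``has_loh`` defaults to exactly
    that); within a cohort the flag is drawn per sample with the
    histology-linked probabilities of the spec.
    """
    if sample_class not in CYTO_CLASSES:
        raise ValueError(f"unknown cytology class {sample_class!r}")
    if has_loh is None:
        has_loh = sample_class == "H+N+"
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    table = _variant_table(rng, spec, has_loh)
    calls = [
        VariantCall(chromosome=c, position=int(p), vaf=float(v))
        for c, p, v in zip(table["chromosome"], table["position"], table["vaf"])
    ]
    return VariantSet(sample_id=sample_id, variants=calls)


def _assign_programs(
    rng: np.random.Generator, spec: CohortSpec, nuclear_genes: list[str]
) -> dict[str, dict[str, float]]:
    """Draw disjoint program gene sets with signed loadings."""
    total = spec.h_program.n_genes + spec.n_program.n_genes + spec.bm_program.n_genes
    if total > len(nuclear_genes):
        raise ValueError("not enough nuclear genes for the requested programs")
    chosen = rng.choice(len(nuclear_genes), size=total, replace=False)
    out: dict[str, dict[str, float]] = {}
    start = 0
    for name, prog in (
        ("h", spec.h_program), ("n", spec.n_program), ("bm", spec.bm_program)
    ):
        idx = chosen[start : start + prog.n_genes]
        start += prog.n_genes
        lo, hi = prog.loading_range
        mag = prog.log2fc * rng.uniform(lo, hi, size=prog.n_genes)
        sign = np.where(rng.random(prog.n_genes) < 0.5, 1.0, -1.0)
        out[name] = {
            nuclear_genes[i]: float(m * s) for i, m, s in zip(idx, mag, sign)
        }
    return out


def generate_cohort(spec: CohortSpec | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort (counts, variants, labels, ledger).

    Deterministic given ``spec.seed``.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    sizes = spec.class_sizes()
    if spec.n_ni_labelled_nneg > sizes["H+N-"]:
        raise ValueError("n_ni_labelled_nneg exceeds the H+N- class size")

    # ---- sample table -----------------------------------------------------
    classes = [c for c, n in sizes.items() for _ in range(n)]
    n_samples = len(classes)
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    hurthle = np.array([c.startswith("H+") for c in classes])
    neoplasm = np.array([c.endswith("N+") for c in classes])

    ni_labelled = np.array([c == "H+N+" for c in classes])
    hpos_nneg_idx = np.flatnonzero(np.array(classes) == "H+N-")
    picked = rng.choice(hpos_nneg_idx, size=spec.n_ni_labelled_nneg, replace=False)
    ni_labelled[picked] = True

    p_mal = np.where(neoplasm, spec.p_malignant_npos, spec.p_malignant_nneg)
    malignant = rng.random(n_samples) < p_mal

    p_loh = np.where(malignant, spec.p_loh_malignant, spec.p_loh_benign)
    has_loh = (np.array(classes) == "H+N+") & (rng.random(n_samples) < p_loh)

    labels = pd.DataFrame(
        {
            "cyto_class": classes,
            "hurthle": hurthle,
            "neoplasm": neoplasm,
            "ni_labelled": ni_labelled,
            "histology": np.where(malignant, "malignant", "benign"),
            "has_loh": has_loh,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # ---- gene annotation --------------------------------------------------
    if spec.n_genes < len(MT_PROTEIN_CODING) + 2 + 50:
        raise ValueError("n_genes too small for a meaningful cohort")
    mt_rrna = ("MT-RNR1", "MT-RNR2")
    n_nuclear = spec.n_genes - len(MT_PROTEIN_CODING) - len(mt_rrna)
    nuclear = [f"G{i + 1:05d}" for i in range(n_nuclear)]
    gene_ids = list(MT_PROTEIN_CODING) + list(mt_rrna) + nuclear
    chrom_col = ["MT"] * (len(MT_PROTEIN_CODING) + len(mt_rrna)) + [
        str(rng.choice(AUTOSOMES)) for _ in nuclear
    ]
    biotype = (
        ["protein_coding"] * len(MT_PROTEIN_CODING)
        + ["Mt_rRNA"] * len(mt_rrna)
        + ["protein_coding"] * n_nuclear
    )
    annotation = pd.DataFrame(
        {"chromosome": chrom_col, "biotype": biotype},
        index=pd.Index(gene_ids, name="gene_id"),
    )

    # ---- expression programs ---------------------------------------------
    programs = _assign_programs(rng, spec, nuclear)
    if spec.mito_log2fc:  # oncocytic mitochondrial elevation, always up
        for g in MT_PROTEIN_CODING:
            programs["h"][g] = programs["h"].get(g, 0.0) + spec.mito_log2fc

    a_h = hurthle.astype(float) + rng.normal(0, spec.h_program.activity_sd, n_samples)
    a_n = (hurthle & neoplasm).astype(float) + rng.normal(
        0, spec.n_program.activity_sd, n_samples
    )
    a_bm = malignant.astype(float) + rng.normal(
        0, spec.bm_program.activity_sd, n_samples
    )

    base = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_genes)
    is_mt = np.isin(gene_ids, MT_PROTEIN_CODING + mt_rrna)
    base[is_mt] *= spec.mito_baseline_scale
    lib = rng.lognormal(0.0, spec.library_log_sd, n_samples)

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    log2shift = np.zeros((spec.n_genes, n_samples))
    for name, activity in (("h", a_h), ("n", a_n), ("bm", a_bm)):
        for g, loading in programs[name].items():
            log2shift[gene_pos[g]] += loading * activity
    mu = base[:, None] * np.exp2(log2shift) * lib[None, :]
    r = 1.0 / spec.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids, dtype=np.int64)
    counts_df.index.name = "gene_id"
    expression = ExpressionMatrix(counts=counts_df, annotation=annotation)

    # ---- variants ---------------------------------------------------------
    variant_tables = {
        sid: _variant_table(rng, spec, bool(loh))
        for sid, loh in zip(sample_ids, has_loh)
    }

    ledger = {
        "seed": spec.seed,
        "class_sizes": sizes,
        "planted_genes": {
            name: dict(sorted(genes.items())) for name, genes in programs.items()
        },
        "loh": {
            "chromosomes": list(spec.loh_chromosomes),
            "fraction": spec.loh_fraction,
            "samples_with_loh": [s for s, f in zip(sample_ids, has_loh) if f],
        },
        "histology": {s: h for s, h in zip(sample_ids, labels["histology"])},
    }
    logger.info(
        "generated cohort: %d samples (%d H+ / %d H-), NI subset %d, %d genes",
        n_samples, int(hurthle.sum()), int((~hurthle).sum()),
        int(ni_labelled.sum()), spec.n_genes,
    )
    return SyntheticCohort(
        expression=expression,
        variant_tables=variant_tables,
        labels=labels,
        ledger=ledger,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Disk round trip
# ---------------------------------------------------------------------------

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    + "".join(f"##contig=<ID={c}>\n" for c in CANONICAL_CHROMOSOMES)
    + '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    + '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
)


def write_sample_vcf(table: pd.DataFrame, sample_id: str, path) -> None:
    """Write one sample's variant table as a VCFv4.2 file with GT:AD fields."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample_id}\n"
        )
        for row in table.itertuples(index=False):
            ref_d, alt_d = int(row.ref_depth), int(row.alt_depth)
            if alt_d == 0:
                gt = "0/0"
            elif ref_d == 0:
                gt = "1/1"
            else:
                gt = "0/1"
            fh.write(
                f"{row.chromosome}\t{int(row.position)}\t.\tA\tG\t.\tPASS\t.\t"
                f"GT:AD\t{gt}:{ref_d},{alt_d}\n"
            )


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write the cohort as plain-text files; read back losslessly by the pipeline.

    Layout: ``counts.tsv``, ``annotation.tsv``, ``labels.tsv``,
    ``ledger.json`` and ``vcf/<sample>.vcf``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "vcf").mkdir(exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "annotation": directory / "annotation.tsv",
        "labels": directory / "labels.tsv",
        "ledger": directory / "ledger.json",
        "vcf_dir": directory / "vcf",
    }
    cohort.expression.counts.to_csv(paths["counts"], sep="\t")
    cohort.expression.annotation.to_csv(paths["annotation"], sep="\t")
    cohort.labels.to_csv(paths["labels"], sep="\t")
    with open(paths["ledger"], "w") as fh:
        json.dump(cohort.ledger, fh, indent=1, sort_keys=True)
        fh.write("\n")
    for sid, table in cohort.variant_tables.items():
        write_sample_vcf(table, sid, paths["vcf_dir"] / f"{sid}.vcf")
    logger.info("wrote cohort to %s", directory)
    return paths


def read_cohort(directory) -> tuple[ExpressionMatrix, dict[str, VariantSet], pd.DataFrame]:
    """Read back a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    annotation = read_annotation(directory / "annotation.tsv")
    expression = read_counts(directory / "counts.tsv", annotation=annotation)
    labels = pd.read_csv(directory / "labels.tsv", sep="\t", index_col=0)
    variant_sets = {
        sid: read_variants_vcf(directory / "vcf" / f"{sid}.vcf", sample_id=sid)
        for sid in labels.index
    }
    return expression, variant_sets, labels


def spec_from_yaml(path) -> CohortSpec:
    """Load a CohortSpec from a YAML mapping of field overrides."""
    import yaml

    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    kwargs = {}
    for key, value in overrides.items():
        if key in ("h_program", "n_program", "bm_program"):
            if isinstance(value.get("loading_range"), list):
                value["loading_range"] = tuple(value["loading_range"])
            kwargs[key] = ProgramSpec(**value)
        elif key in ("loh_chromosomes",):
            kwargs[key] = tuple(str(c) for c in value)
        elif key == "baseline_vaf_beta":
            kwargs[key] = tuple(float(v) for v in value)
        else:
            kwargs[key] = value
    return CohortSpec(**kwargs)


def spec_to_dict(spec: CohortSpec) -> dict:
    return asdict(spec)
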