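"""Expressed loss-of-heterozygosity (LOH) statistics from RNA-seq variant calls.

LOH in a tumor shifts variant allele fractions (VAFs) away from the
heterozygous expectation of 0.5. Because RNA-seq variants are confined to
expressed exons, no segment boundaries are estimated here: the statistic is
the proportion of putatively heterozygous variants whose VAF lies far from
0.5, computed per chromosome and pooled over the autosomes ("genome-level").

Definitions, for a collection of VAFs after dropping calls with VAF exactly 1
(expressed homozygous sites carry no heterozygosity information)::

    n_all_het  = #{ 0 < vaf < 1 }
    n_loss_het = #{ 0 < vaf < 0.2  or  0.8 < vaf < 1 }
    LOH        = n_loss_het / n_all_het

All inequalities are strict; VAFs exactly 0, 0.2, 0.8 or 1 never count as
loss, and VAFs exactly 0 or 1 are not heterozygous candidates. When
``n_all_het == 0`` the statistic is undefined and reported as NaN rather
than 0 -- an empty chromosome is absence of evidence, not evidence of
retained heterozygosity. Genome-level LOH pools chromosomes 1-22 only; the
mitochondrial genome and the sex chromosomes are excluded (effectively
haploid or heteroplasmic, so their VAF spectrum is uninformative for LOH).
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical human chromosome labels (unprefixed, mitochondrial genome = MT).
AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
CANONICAL_CHROMOSOMES: tuple[str, ...] = AUTOSOMES + ("X", "Y", "MT")

#: The 15 chromosomes whose chromosome-level LOH enters the neoplasm-index
#: feature vector, followed by genome-level LOH (16 features in total).
NI_CHROMOSOMES: tuple[str, ...] = (
    "1", "2", "3", "4", "5", "6", "8", "9",
    "11", "13", "14", "15", "16", "18", "19",
)

LOSS_LOW = 0.2
LOSS_HIGH = 0.8


def normalize_chromosome(label: str) -> str:
    """Normalize a chromosome label to the unprefixed dialect.

    Accepts ``"chr1"``/``"1"`` and ``"chrM"``/``"M"``/``"MT"`` spellings.

    Raises
    ------
    ValueError
        If the label is not one of the 25 canonical human chromosomes.
    """
    name = str(label).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    name = name.upper()
    if name == "M":
        name = "MT"
    if name not in CANONICAL_CHROMOSOMES:
        raise ValueError(f"not a canonical human chromosome label: {label!r}")
    return name


@dataclass(frozen=True)
class VariantCall:
    """A single biallelic variant call: chromosome, 1-based position, VAF."""

    chromosome: str
    position: int
    vaf: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"VAF must lie in [0, 1], got {self.vaf!r}")
        if self.position < 1:
            raise ValueError(f"position must be 1-based positive, got {self.position!r}")


@dataclass
class VariantSet:
    """Per-sample collection of variant calls, the substrate of the LOH statistic."""

    sample_id: str
    variants: list[VariantCall] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.variants)

    def vafs(self, chromosome: str | None = None) -> np.ndarray:
        """VAFs of all variants, or of one (normalized) chromosome."""
        if chromosome is None:
            return np.array([v.vaf for v in self.variants], dtype=float)
        chromosome = normalize_chromosome(chromosome)
        return np.array(
            [v.vaf for v in self.variants if v.chromosome == chromosome], dtype=float
        )

    def autosomal_vafs(self) -> np.ndarray:
        return np.array(
            [v.vaf for v in self.variants if v.chromosome in AUTOSOMES], dtype=float
        )


@dataclass
class LOHProfile:
    """Chromosome-level and genome-level LOH values for one sample (NaN = undefined)."""

    sample_id: str
    per_chromosome: dict[str, float]
    genome: float
    n_all_het: dict[str, int] = field(default_factory=dict)


def loh_statistic(vafs: Iterable[float]) -> float:
    """LOH statistic for a collection of VAFs; NaN when no heterozygous candidate.

    See module docstring for the definition. Input VAFs must lie in [0, 1].
    """
    v = np.asarray(list(vafs), dtype=float)
    if v.size and (np.nanmin(v) < 0.0 or np.nanmax(v) > 1.0):
        raise ValueError("VAFs must lie in [0, 1]")
    v = v[v != 1.0]  # pre-filter homozygous-looking calls
    het = (v > 0.0) & (v < 1.0)
    n_all_het = int(het.sum())
    if n_all_het == 0:
        return math.nan
    loss = ((v > 0.0) & (v < LOSS_LOW)) | ((v > LOSS_HIGH) & (v < 1.0))
    return float(loss.sum()) / n_all_het


def heterozygous_count(vafs: Iterable[float]) -> int:
    """``n_all_het`` for a collection of VAFs (after the VAF==1 pre-filter)."""
    v = np.asarray(list(vafs), dtype=float)
    v = v[v != 1.0]
    return int(((v > 0.0) & (v < 1.0)).sum())


def chromosome_loh(variant_set: VariantSet, chromosome: str) -> float:
    """LOH statistic restricted to one chromosome (NaN if no usable variants)."""
    return loh_statistic(variant_set.vafs(chromosome))


def genome_loh(variant_set: VariantSet) -> float:
    """Genome-level LOH over pooled autosomal (1-22) VAFs; MT/X/Y are excluded."""
    return loh_statistic(variant_set.autosomal_vafs())


def loh_profile(variant_set: VariantSet) -> LOHProfile:
    """Full per-chromosome + genome LOH profile with heterozygous-candidate counts."""
    per_chrom: dict[str, float] = {}
    n_het: dict[str, int] = {}
    for chrom in CANONICAL_CHROMOSOMES:
        vafs = variant_set.vafs(chrom)
        per_chrom[chrom] = loh_statistic(vafs)
        n_het[chrom] = heterozygous_count(vafs)
    return LOHProfile(
        sample_id=variant_set.sample_id,
        per_chromosome=per_chrom,
        genome=genome_loh(variant_set),
        n_all_het=n_het,
    )


def loh_feature_vector(
    variant_set: VariantSet,
    chromosome_list: Sequence[str] = NI_CHROMOSOMES,
    impute: float | None = None,
) -> np.ndarray:
    """LOH feature vector: chromosome-level values in list order, then genome-level.

    With the default chromosome list this is the 16-element neoplasm-index
    LOH feature block. Undefined values are NaN unless ``impute`` is given
    (classifiers use 0.0 = "no LOH signal"; the imputation count is logged).
    """
    values = [chromosome_loh(variant_set, c) for c in chromosome_list]
    values.append(genome_loh(variant_set))
    vec = np.asarray(values, dtype=float)
    if impute is not None:
        n_missing = int(np.isnan(vec).sum())
        if n_missing:
            logger.info(
                "sample %s: imputing %d undefined LOH feature(s) as %g",
                variant_set.sample_id, n_missing, impute,
            )
            vec = np.where(np.isnan(vec), impute, vec)
    return vec


def loh_feature_table(
    variant_sets: Mapping[str, VariantSet] | Iterable[VariantSet],
    chromosome_list: Sequence[str] = NI_CHROMOSOMES,
    impute: float | None = 0.0,
) -> pd.DataFrame:
    """Samples x LOH-features table (columns ``loh_chr<k>`` ... ``loh_genome``)."""
    if isinstance(variant_sets, Mapping):
        sets = list(variant_sets.values())
    else:
        sets = list(variant_sets)
    cols = [f"loh_chr{c}" for c in chromosome_list] + ["loh_genome"]
    rows = {vs.sample_id: loh_feature_vector(vs, chromosome_list, impute=impute)
            for vs in sets}
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def loh_profile_table(variant_sets: Iterable[VariantSet]) -> pd.DataFrame:
    """Samples x (chr1..chr22, genome) LOH table, e.g. for heatmap display."""
    records = {}
    for vs in variant_sets:
        prof = loh_profile(vs)
        row = {f"chr{c}": prof.per_chromosome[c] for c in AUTOSOMES}
        row["genome"] = prof.genome
        records[vs.sample_id] = row
    return pd.DataFrame.from_dict(records, orient="index")


def write_loh_tsv(profiles: Iterable[LOHProfile], path) -> None:
    """Write per-sample LOH profiles as TSV (sample_id, chr1..chr22, genome)."""
    rows = []
    for prof in profiles:
        row: dict[str, object] = {"sample_id": prof.sample_id}
        row.update({f"chr{c}": prof.per_chromosome[c] for c in AUTOSOMES})
        row["genome"] = prof.genome
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_variants_vcf(
    path,
    sample_id: str | None = None,
    include_nonpass: bool = False,
) -> VariantSet:
    """Read one sample's biallelic variant calls from a VCF (v4.x, optionally gzipped).

    VAF source precedence per record: a dedicated per-sample allele-fraction
    FORMAT field (``AF``, then ``VAF``) if present, else allele depths
    (``AD``) as alt / (ref + alt). Multi-allelic records, records on
    non-canonical contigs, non-PASS records (unless ``include_nonpass``) and
    records without usable depth/fraction information are skipped; skip
    counts are logged.

    Parameters
    ----------
    sample_id
        Sample column to read. May be omitted for single-sample VCFs; the
        returned set is always labelled with the actual sample used (or the
        given identifier if the VCF is sample-less).
    """
    import pysam

    try:
        vcf = pysam.VariantFile(str(path))
    except NotImplementedError:
        # plain gzip (not bgzip) is not seekable for htslib; decompress first
        import shutil
        import tempfile

        with gzip.open(str(path), "rb") as src, tempfile.NamedTemporaryFile(
            suffix=".vcf", delete=False
        ) as tmp:
            shutil.copyfileobj(src, tmp)
            tmp_path = tmp.name
        vcf = pysam.VariantFile(tmp_path)
    samples = list(vcf.header.samples)
    if sample_id is not None and sample_id in samples:
        column = sample_id
    elif len(samples) == 1:
        column = samples[0]
    elif not samples:
        raise ValueError(f"VCF {path} has no sample columns")
    else:
        raise ValueError(
            f"VCF {path} has {len(samples)} samples; specify sample_id among {samples}"
        )

    out_id = sample_id if sample_id is not None else column
    calls: list[VariantCall] = []
    skipped = {"non_canonical": 0, "multiallelic": 0, "filtered": 0, "no_vaf": 0}
    for rec in vcf:
        try:
            chrom = normalize_chromosome(rec.chrom)
        except ValueError:
            skipped["non_canonical"] += 1
            continue
        if rec.alts is None or len(rec.alts) != 1:
            skipped["multiallelic"] += 1
            continue
        if not include_nonpass:
            filters = list(rec.filter.keys())
            if filters and filters != ["PASS"]:
                skipped["filtered"] += 1
                continue
        fmt = rec.samples[column]
        vaf = _extract_vaf(fmt)
        if vaf is None:
            skipped["no_vaf"] += 1
            continue
        calls.append(VariantCall(chromosome=chrom, position=rec.pos, vaf=vaf))
    vcf.close()

    n_skipped = sum(skipped.values())
    if n_skipped:
        logger.info("VCF %s sample %s: skipped %d records (%s)",
                    path, out_id, n_skipped, skipped)
    if not calls:
        logger.warning("VCF %s sample %s: zero usable variant records", path, out_id)
    return VariantSet(sample_id=out_id, variants=calls)


def _extract_vaf(fmt) -> float | None:
    """Per-sample VAF: dedicated fraction field first, else AD-derived."""
    for key in ("AF", "VAF"):
        if key in fmt:
            val = fmt[key]
            if isinstance(val, (tuple, list)):
                val = val[0] if val else None
            if val is not None and not (isinstance(val, float) and math.isnan(val)):
                val = float(val)
                if 0.0 <= val <= 1.0:
                    return val
    if "AD" in fmt:
        ad = fmt["AD"]
        if ad is not None and len(ad) >= 2 and ad[0] is not None and ad[1] is not None:
            ref, alt = int(ad[0]), int(ad[1])
            if ref + alt > 0:
                return alt / (ref + alt)
    return None


def open_maybe_gzip(path, mode: str = "rt"):
    """Open a plain or gzip-compressed text file."""
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)
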