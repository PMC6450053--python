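"""Count-matrix handling, normalization and differential-expression feature selection.

The classifier stack consumes gene-level RNA-seq counts. Differential
expression between two sample groups is tested on raw counts with a
negative-binomial exact test (common-then-tagwise shrunken dispersion,
conditional on the per-gene total after equalizing library sizes), while the
downstream SVM indices consume variance-stabilized values.

The variance-stabilizing transform (VST) uses the closed form implied by the
parametric mean-dispersion trend alpha(mu) = a0/mu + a1: with
Var = (1 + a0) mu + a1 mu^2, integrating 1/sqrt(Var) gives

    vst(q) = log2( (1 + a0 + 2 a1 q + 2 sqrt(a1 q (1 + a0 + a1 q))) / (4 a1) )

which is monotone in the normalized count q and approaches log2(q) + const
at high counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .variant_loh import normalize_chromosome

logger = logging.getLogger(__name__)

#: The 13 protein-coding genes of the human mitochondrial genome. All 13 are
#: captured by the assay and all 13 are force-included in the Hurthle-index
#: candidate feature set (oncocytes are defined by mitochondrial abundance).
MT_PROTEIN_CODING: tuple[str, ...] = (
    "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND4L", "MT-ND5", "MT-ND6",
    "MT-CO1", "MT-CO2", "MT-CO3", "MT-ATP6", "MT-ATP8", "MT-CYB",
)


class CountFormatError(ValueError):
    """Raised for malformed count input (negative/non-numeric entries, duplicates)."""


@dataclass
class ExpressionMatrix:
    """Genes x samples count matrix with gene annotation and optional normalized values.

    ``annotation`` is indexed by gene identifier with at least a
    ``chromosome`` column and (ideally) a ``biotype`` column; it may be None
    for operations that do not need it.
    """

    counts: pd.DataFrame
    annotation: pd.DataFrame | None = None
    normalized: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dupes = c.index[c.index.duplicated()].unique().tolist()
            raise CountFormatError(f"duplicate gene identifiers: {dupes[:5]}")
        if c.columns.duplicated().any():
            dupes = c.columns[c.columns.duplicated()].unique().tolist()
            raise CountFormatError(f"duplicate sample identifiers: {dupes[:5]}")
        _validate_count_values(c)
        if self.normalized is not None and self.normalized.shape != c.shape:
            raise ValueError("normalized matrix shape differs from counts")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


def _validate_count_values(df: pd.DataFrame) -> None:
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        numeric = df.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(numeric.isna().to_numpy() & df.notna().to_numpy())
        if bad.size:
            g, s = bad[0]
            raise CountFormatError(
                f"non-numeric count at gene {df.index[g]!r}, sample {df.columns[s]!r}: "
                f"{df.iat[g, s]!r}"
            )
        arr = numeric.to_numpy()
    if np.isnan(arr).any():
        g, s = np.argwhere(np.isnan(arr))[0]
        raise CountFormatError(f"missing count at gene {df.index[g]!r}, sample {df.columns[s]!r}")
    if (arr < 0).any():
        g, s = np.argwhere(arr < 0)[0]
        raise CountFormatError(
            f"negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}: {arr[g, s]}"
        )
    if not np.allclose(arr, np.round(arr)):
        g, s = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise CountFormatError(
            f"non-integer count at gene {df.index[g]!r}, sample {df.columns[s]!r}: {arr[g, s]}"
        )


def read_counts(path, annotation: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Read a genes x samples count matrix from TSV/CSV or MatrixMarket triplet.

    For a ``.mtx`` file, sidecar files ``<stem>.genes.txt`` and
    ``<stem>.samples.txt`` (one identifier per line) are expected next to it.
    """
    path = str(path)
    if path.endswith(".mtx"):
        from scipy.io import mmread

        stem = path[: -len(".mtx")]
        genes = [l.strip() for l in open(stem + ".genes.txt") if l.strip()]
        samples = [l.strip() for l in open(stem + ".samples.txt") if l.strip()]
        mat = np.asarray(mmread(path).todense())
        if mat.shape != (len(genes), len(samples)):
            raise CountFormatError(
                f"MTX shape {mat.shape} does not match sidecars "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        sep = "," if path.endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
    _validate_count_values(df)
    df = df.apply(pd.to_numeric).round().astype(np.int64)
    matrix = ExpressionMatrix(counts=df, annotation=annotation)
    if annotation is not None:
        unknown = df.index.difference(annotation.index)
        if len(unknown):
            logger.warning("%d gene(s) missing from annotation (e.g. %s)",
                           len(unknown), list(unknown[:3]))
    return matrix


def read_annotation(path) -> pd.DataFrame:
    """Read a gene annotation TSV (gene_id, chromosome, biotype)."""
    ann = pd.read_csv(path, sep="\t", index_col=0)
    if "chromosome" not in ann.columns:
        raise CountFormatError("annotation must have a 'chromosome' column")
    return ann


def write_counts_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.counts.to_csv(path, sep="\t")


def size_factors(
    matrix: ExpressionMatrix | pd.DataFrame, pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    For each sample, the median over genes of count / geometric-mean-across-
    samples, using genes with strictly positive counts in every sample. With
    ``pseudo_reference=True`` the geometric mean is taken over nonzero
    entries only, rescuing sparse matrices with no all-positive gene.
    """
    counts = matrix.counts if isinstance(matrix, ExpressionMatrix) else matrix
    arr = counts.to_numpy(dtype=float)
    all_positive = (arr > 0).all(axis=1)
    if not pseudo_reference:
        if not all_positive.any():
            raise ValueError(
                "no gene has positive counts in all samples; "
                "retry with pseudo_reference=True"
            )
        sub = arr[all_positive]
        ref = np.exp(np.mean(np.log(sub), axis=1))
        ratios = sub / ref[:, None]
    else:
        with np.errstate(divide="ignore"):
            logs = np.where(arr > 0, np.log(arr), np.nan)
        log_ref = np.nanmean(logs, axis=1)
        usable = np.isfinite(log_ref)
        with np.errstate(invalid="ignore"):
            ratios = np.where(arr[usable] > 0,
                              arr[usable] / np.exp(log_ref[usable])[:, None], np.nan)
    sf = np.nanmedian(ratios, axis=0)
    if not np.all(np.isfinite(sf)) or (sf <= 0).any():
        raise ValueError("size factor estimation failed (non-positive factor)")
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _fit_dispersion_trend(mu: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of disp ~ a0/mu + a1 with one outlier-trimming pass."""
    X = np.column_stack([1.0 / mu, np.ones_like(mu)])
    keep = np.ones(len(mu), dtype=bool)
    a0 = a1 = None
    for _ in range(3):
        coef, *_ = np.linalg.lstsq(X[keep], disp[keep], rcond=None)
        a0, a1 = coef
        resid = disp - X @ coef
        scale = np.median(np.abs(resid[keep])) + 1e-12
        new_keep = np.abs(resid) < 6 * scale
        if new_keep.sum() < 10 or new_keep.all() or (new_keep == keep).all():
            keep = new_keep if new_keep.sum() >= 10 else keep
            break
        keep = new_keep
    a0 = float(max(a0, 0.0))
    a1 = float(max(a1, 1e-4))
    return a0, a1


def vst_transform(
    matrix: ExpressionMatrix,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Variance-stabilizing transform of the count matrix (approximately log2 scale).

    Gene-wise dispersions are estimated by moments on size-factor-normalized
    counts, a parametric trend alpha(mu) = a0/mu + a1 is fitted across genes,
    and the closed-form transform for that trend is applied (see module
    docstring). Falls back to log2(q + 1) with a warning when fewer than 10
    genes support the trend fit. Also stored on ``matrix.normalized``.
    """
    if factors is None:
        factors = size_factors(matrix)
    q = matrix.counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]

    mu = q.mean(axis=1)
    var = q.var(axis=1, ddof=1) if q.shape[1] > 1 else np.zeros_like(mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (var - mu) / mu**2
    usable = (mu > 5.0) & np.isfinite(disp) & (disp > 0)
    if usable.sum() < 10:
        warnings.warn(
            "dispersion trend not estimable (<10 usable genes); "
            "falling back to log2(normalized count + 1)",
            RuntimeWarning,
        )
        out = np.log2(q + 1.0)
    else:
        a0, a1 = _fit_dispersion_trend(mu[usable], disp[usable])
        out = np.log2(
            (1.0 + a0 + 2.0 * a1 * q + 2.0 * np.sqrt(a1 * q * (1.0 + a0 + a1 * q)))
            / (4.0 * a1)
        )
    norm = pd.DataFrame(out, index=matrix.counts.index, columns=matrix.counts.columns)
    matrix.normalized = norm
    return norm


def mito_gene_set(annotation: pd.DataFrame) -> list[str]:
    """Identifiers of the mitochondrial protein-coding genes present in the annotation.

    Selects genes on chromosome MT with biotype ``protein_coding`` (rRNA/tRNA
    mitochondrial genes are excluded). Warns listing any of the 13 canonical
    genes that are absent.
    """
    def _is_mt(label) -> bool:
        try:
            return normalize_chromosome(label) == "MT"
        except ValueError:
            return False

    on_mt = annotation.index[annotation["chromosome"].map(_is_mt)]
    if "biotype" in annotation.columns:
        on_mt = [g for g in on_mt if annotation.loc[g, "biotype"] == "protein_coding"]
    else:
        on_mt = list(on_mt)
    missing = sorted(set(MT_PROTEIN_CODING) - set(on_mt))
    if missing:
        warnings.warn(
            f"annotation is missing {len(missing)} mitochondrial protein-coding "
            f"gene(s): {missing}",
            RuntimeWarning,
        )
    return list(on_mt)


# ---------------------------------------------------------------------------
# Differential expression: NB exact test with shrunken dispersions
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    """Per-gene differential-expression results.

    ``table`` is indexed by gene with columns ``log2_fc`` (positive = higher
    in the positive group), ``p_value``, ``fdr`` (Benjamini-Hochberg) and
    ``dispersion`` (tagwise NB dispersion used by the test).
    """

    table: pd.DataFrame
    positive_group: object = True
    backend: str = "exact"

    def __post_init__(self) -> None:
        t = self.table
        if ((t["p_value"] < -1e-12) | (t["p_value"] > 1 + 1e-12)).any():
            raise ValueError("p-values outside [0, 1]")
        if (t["fdr"] + 1e-12 < t["p_value"]).any():
            raise ValueError("FDR-adjusted p-values must be >= raw p-values")


def _group_conditional_loglik(y: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Conditional NB log-likelihood of one group's counts given their total.

    ``y`` is genes x samples (equalized libraries), ``r`` a grid of inverse
    dispersions; returns genes x len(r).
    """
    n = y.shape[1]
    z = y.sum(axis=1)
    # sum_i lgamma(y_i + r) term: genes x K
    term = gammaln(y[:, :, None] + r[None, None, :]).sum(axis=1)
    out = (
        term
        - n * gammaln(r)[None, :]
        + gammaln(n * r)[None, :]
        - gammaln(z[:, None] + n * r[None, :])
    )
    return out


def _conditional_loglik_grid(
    ya: np.ndarray, yb: np.ndarray, phi_grid: np.ndarray, chunk: int = 512
) -> np.ndarray:
    """Summed two-group conditional log-likelihood per gene over a dispersion grid."""
    r = 1.0 / phi_grid
    G = ya.shape[0]
    out = np.empty((G, len(phi_grid)))
    for start in range(0, G, chunk):
        sl = slice(start, min(start + chunk, G))
        out[sl] = _group_conditional_loglik(ya[sl], r) + _group_conditional_loglik(
            yb[sl], r
        )
    return out


def exact_nb_test(ya: np.ndarray, yb: np.ndarray, dispersion: float) -> float:
    """Two-sided NB exact test p-value for one gene, at a given dispersion.

    Conditions on the total count: with equal per-sample library sizes the
    group sums are NB with means n_k * mu and sizes n_k / phi, and the
    p-value is the total conditional probability of all splits of the
    observed total whose probability does not exceed that of the observed
    split.
    """
    ya = np.asarray(ya, dtype=float)
    yb = np.asarray(yb, dtype=float)
    na, nb = len(ya), len(yb)
    za, zb = ya.sum(), yb.sum()
    z = za + zb
    if z == 0:
        return 1.0
    mu = z / (na + nb)
    ra, rb = na / dispersion, nb / dispersion
    pa = ra / (ra + na * mu)
    pb = rb / (rb + nb * mu)
    a = np.arange(int(z) + 1, dtype=float)
    logf = stats.nbinom.logpmf(a, ra, pa) + stats.nbinom.logpmf(z - a, rb, pb)
    log_obs = logf[int(za)]
    total = logsumexp(logf)
    keep = logf <= log_obs + 1e-10
    return float(min(1.0, np.exp(logsumexp(logf[keep]) - total)))


def differential_expression(
    matrix: ExpressionMatrix,
    group_labels,
    backend: str = "exact",
    tagwise_prior_weight: float = 10.0,
    lfc_prior_count: float = 2.0,
) -> DEResult:
    """Negative-binomial differential expression between two sample groups.

    Parameters
    ----------
    group_labels
        Boolean array/Series aligned to the sample columns; True marks the
        positive group (log2 fold-changes are positive-over-negative).
    backend
        ``"exact"`` (default): conditional NB exact test, summing the
        probabilities of splits as or less probable than the observed one.
        ``"lr"``: NB likelihood-ratio test at the same tagwise dispersions
        (chi-square with 1 df), a fast documented alternative.

    Library sizes are equalized by scaling counts to the geometric-mean
    effective library (median-of-ratios factors) and rounding; dispersions
    are estimated by conditional maximum likelihood, common first and then
    shrunk tagwise toward the common value by weighted likelihood.
    """
    counts = matrix.counts
    if isinstance(group_labels, pd.Series):
        group_labels = group_labels.reindex(counts.columns).to_numpy()
    labels = np.asarray(group_labels)
    if labels.dtype != bool:
        uniq = np.unique(labels)
        if len(uniq) != 2:
            raise ValueError(f"expected exactly two groups, got {len(uniq)}")
        labels = labels == uniq[1]
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("each group needs >= 2 samples to estimate dispersion")

    sf = size_factors(matrix, pseudo_reference=True)
    scale = np.exp(np.mean(np.log(sf))) / sf.to_numpy()
    pseudo = np.rint(counts.to_numpy(dtype=float) * scale[None, :])
    ya = pseudo[:, labels]
    yb = pseudo[:, ~labels]

    phi_grid = np.logspace(-4, 0.9, 48)
    cl = _conditional_loglik_grid(ya, yb, phi_grid)
    common_idx = int(np.argmax(cl.sum(axis=0)))
    mean_cl = cl.mean(axis=0)
    # tagwise: per-gene weighted likelihood, shrunk toward the common curve
    obj = cl + tagwise_prior_weight * mean_cl[None, :]
    phi_tag = phi_grid[np.argmax(obj, axis=1)]
    logger.debug("common dispersion %.4g", phi_grid[common_idx])

    mean_a = ya.mean(axis=1)
    mean_b = yb.mean(axis=1)
    log2_fc = np.log2(mean_a + lfc_prior_count) - np.log2(mean_b + lfc_prior_count)

    if backend == "exact":
        pvals = np.array(
            [exact_nb_test(ya[g], yb[g], phi_tag[g]) for g in range(len(pseudo))]
        )
    elif backend == "lr":
        pvals = _lr_test(ya, yb, phi_tag)
    else:
        raise ValueError(f"unknown backend {backend!r}")

    fdr = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"log2_fc": log2_fc, "p_value": pvals, "fdr": fdr, "dispersion": phi_tag},
        index=counts.index,
    )
    return DEResult(table=table, backend=backend)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, r: np.ndarray) -> np.ndarray:
    """NB log-likelihood summed over samples; y genes x samples, mu/r per gene."""
    mu = np.maximum(mu, 1e-8)[:, None]
    r = r[:, None]
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    ).sum(axis=1)


def _lr_test(ya: np.ndarray, yb: np.ndarray, phi: np.ndarray) -> np.ndarray:
    r = 1.0 / phi
    mu_a, mu_b = ya.mean(axis=1), yb.mean(axis=1)
    mu0 = np.concatenate([ya, yb], axis=1).mean(axis=1)
    l1 = _nb_loglik(ya, mu_a, r) + _nb_loglik(yb, mu_b, r)
    l0 = _nb_loglik(ya, mu0, r) + _nb_loglik(yb, mu0, r)
    lr = np.maximum(2.0 * (l1 - l0), 0.0)
    return stats.chi2.sf(lr, df=1)


def select_features(
    de_result: DEResult,
    fdr_cut: float = 0.05,
    lfc_cut: float = 1.5,
    two_sided: bool = True,
    force_include: Sequence[str] = (),
    max_genes: int | None = None,
) -> list[str]:
    """Genes with adjusted p < ``fdr_cut`` and |log2FC| > ``lfc_cut`` (strict).

    With ``two_sided=False`` only positive fold-changes qualify. The forced
    set (e.g. the 13 mitochondrial protein-coding genes for the Hurthle
    index) is unioned in afterwards. ``max_genes`` keeps the top genes by
    p-value after filtering.

    Raises
    ------
    ValueError
        If the final selection is empty -- relax the thresholds; a classifier
        needs at least one feature.
    """
    t = de_result.table
    fc = t["log2_fc"].abs() if two_sided else t["log2_fc"]
    mask = (t["fdr"] < fdr_cut) & (fc > lfc_cut)
    selected = t.index[mask]
    if max_genes is not None and len(selected) > max_genes:
        selected = t.loc[selected].nsmallest(max_genes, "p_value").index
    genes = list(selected)
    for g in force_include:
        if g not in genes:
            genes.append(g)
    if not genes:
        raise ValueError(
            "feature selection returned no genes; relax fdr_cut/lfc_cut "
            "(a model needs at least one feature)"
        )
    return genes
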