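"""Within-group co-expression structure of plasma miRNAs.

Pairwise Pearson correlations of ΔCT values are computed within each
exposure group, masked at raw p ≥ 0.05, ordered by complete-linkage
hierarchical clustering on 1 − r, and summarized as significant-pair
counts whose stability is assessed by a subject-level bootstrap.  Genomic
coordinates from a miRBase-dialect GFF3 annotate each miRNA with its
chromosome so cross-chromosome correlation enrichment (exposed vs control)
can be tabulated — the readout used to argue for exposure-induced
co-transcription across chromosomes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import complete, leaves_list
from scipy.spatial.distance import squareform

CORRELATION_ALPHA = 0.05


@dataclass
class MiRNALocus:
    """One genomic locus of a mature miRNA (1-based inclusive coordinates).

    A mature miRNA duplicated in the genome yields several loci sharing a
    MIMAT accession; ``copy_index`` numbers them (0, 1, ...) in file order,
    matching the ".1" suffix convention for chromosomal duplications.
    """

    mimat_id: str
    name: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    copy_index: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.mimat_id}: start > end")
        if not self.chromosome:
            raise ValueError(f"{self.mimat_id}: empty chromosome")


@dataclass
class CorrelationSummary:
    r: pd.DataFrame
    p: pd.DataFrame
    mask: pd.DataFrame            # True where p < alpha (significant)
    n_significant: int
    order: list[str]              # complete-linkage leaf order
    n_subjects: int
    alpha: float = CORRELATION_ALPHA
    bootstrap_counts: np.ndarray | None = None
    ci: tuple[float, float] | None = None
    sd_band: tuple[float, float] | None = None


def _pearson_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlation and p-value matrices over columns of X (subjects × miRNAs).

    p-values use the exact t transform with n−2 df.  Constant columns give
    undefined r; those entries are returned as r=0, p=1 (non-significant).
    """
    n = X.shape[0]
    sd = X.std(axis=0)
    degenerate = sd == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(X, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    rr = np.clip(r, -0.9999999999, 0.9999999999)
    t = rr * np.sqrt((n - 2) / (1.0 - rr**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    np.fill_diagonal(p, 0.0)
    if degenerate.any():
        p[degenerate, :] = 1.0
        p[:, degenerate] = 1.0
    return r, p


def masked_correlations(
    delta_ct: pd.DataFrame,
    groups: pd.Series | None = None,
    group: str | None = None,
    alpha: float = CORRELATION_ALPHA,
) -> CorrelationSummary:
    """Pearson correlations among miRNAs for the subjects of one group.

    ``delta_ct`` is miRNA × sample.  Entries with p ≥ alpha are masked
    (NaN) in the returned r matrix copy; the count of significant pairs is
    over the strict upper triangle.
    """
    if groups is not None and group is not None:
        cols = delta_ct.columns[(groups.reindex(delta_ct.columns) == group).to_numpy()]
        delta_ct = delta_ct[cols]
    n = delta_ct.shape[1]
    if n < 4:
        raise ValueError("need ≥ 4 subjects for within-group correlations")
    ids = list(delta_ct.index)
    X = delta_ct.to_numpy(dtype=float).T
    if (X.std(axis=0) == 0).any():
        warnings.warn("constant miRNA: correlations treated as non-significant",
                      stacklevel=2)
    r, p = _pearson_matrix(X)
    sig = p < alpha
    np.fill_diagonal(sig, False)
    iu = np.triu_indices(len(ids), k=1)
    n_sig = int(sig[iu].sum())
    masked = r.copy()
    masked[~(sig | np.eye(len(ids), dtype=bool))] = np.nan

    order = _cluster_order(r, ids)
    return CorrelationSummary(
        r=pd.DataFrame(masked, index=ids, columns=ids),
        p=pd.DataFrame(p, index=ids, columns=ids),
        mask=pd.DataFrame(sig, index=ids, columns=ids),
        n_significant=n_sig,
        order=order,
        n_subjects=n,
        alpha=alpha,
    )


def _cluster_order(r: np.ndarray, ids: list[str]) -> list[str]:
    """Complete-linkage leaf order on distance 1 − r."""
    if len(ids) < 3:
        return list(ids)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    link = complete(squareform(d, checks=False))
    return [ids[i] for i in leaves_list(link)]


def significant_pair_count(delta_ct: pd.DataFrame, alpha: float = CORRELATION_ALPHA) -> int:
    """Number of significant pairs (upper triangle) without the clustering."""
    X = delta_ct.to_numpy(dtype=float).T
    _, p = _pearson_matrix(X)
    iu = np.triu_indices(delta_ct.shape[0], k=1)
    return int((p[iu] < alpha).sum())


def bootstrap_pair_count_stability(
    delta_ct: pd.DataFrame,
    n_boot: int = 1000,
    ci_level: float = 0.99,
    seed: int = 0,
    alpha: float = CORRELATION_ALPHA,
) -> dict:
    """Subject-resampling bootstrap of the significant-pair count.

    Returns the bootstrap distribution, the percentile CI at ``ci_level``
    and a mean ± SD band of the distribution.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be ≥ 100")
    rng = np.random.default_rng(seed)
    X = delta_ct.to_numpy(dtype=float).T
    n = X.shape[0]
    iu = np.triu_indices(X.shape[1], k=1)
    counts = np.empty(n_boot)
    for b in range(n_boot):
        take = rng.integers(0, n, size=n)
        _, p = _pearson_matrix(X[take])
        counts[b] = (p[iu] < alpha).sum()
    tail = (1.0 - ci_level) / 2.0
    ci = (float(np.percentile(counts, 100 * tail)),
          float(np.percentile(counts, 100 * (1 - tail))))
    mu, sd = float(counts.mean()), float(counts.std(ddof=1))
    return {"distribution": counts, "ci": ci, "sd_band": (mu - sd, mu + sd), "mean": mu}


# ---------------------------------------------------------------------------
# Genomic annotation

def load_loci_gff3(path) -> list[MiRNALocus]:
    """Read mature-miRNA loci from a miRBase-dialect GFF3.

    One locus per ``miRNA`` feature line; the MIMAT accession is taken from
    the ``Alias`` attribute (falling back to ``ID``), the name from
    ``Name``.  Loci sharing a MIMAT get incrementing ``copy_index`` in file
    order.  Malformed lines raise with their line number.
    """
    loci: list[MiRNALocus] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype != "miRNA":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinates") from exc
            kv = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    kv[k.strip()] = v.strip()
            mimat = kv.get("Alias") or kv.get("ID")
            if not mimat:
                raise ValueError(f"line {lineno}: no Alias/ID attribute")
            mimat = mimat.split("_")[0]
            idx = seen.get(mimat, 0)
            seen[mimat] = idx + 1
            loci.append(
                MiRNALocus(
                    mimat_id=mimat,
                    name=kv.get("Name", mimat),
                    chromosome=chrom,
                    start=start_i,
                    end=end_i,
                    strand=strand if strand in "+-" else "+",
                    copy_index=idx,
                )
            )
    return loci


def write_loci_gff3(loci: list[MiRNALocus], path) -> None:
    """Write loci in the same miRBase GFF3 dialect that ``load_loci_gff3`` reads."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            suffix = f"_{loc.copy_index}" if loc.copy_index else ""
            attrs = f"ID={loc.mimat_id}{suffix};Alias={loc.mimat_id};Name={loc.name}"
            fh.write(
                f"{loc.chromosome}\t.\tmiRNA\t{loc.start}\t{loc.end}\t.\t"
                f"{loc.strand}\t.\t{attrs}\n"
            )


def chromosomal_cluster_flags(loci: list[MiRNALocus], window: int = 10_000) -> dict:
    """Flag loci lying within ``window`` bp of another miRNA locus on the
    same chromosome (gap between nearest coordinates, 0 if overlapping)."""
    flags = {}
    by_chrom: dict[str, list[MiRNALocus]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chromosome, []).append(loc)
    for chrom, group in by_chrom.items():
        for a in group:
            near = False
            for b in group:
                if b is a:
                    continue
                gap = max(0, max(a.start, b.start) - min(a.end, b.end))
                if gap <= window:
                    near = True
                    break
            flags[(a.mimat_id, a.copy_index)] = near
    return flags


def _loci_by_mimat(loci: list[MiRNALocus]) -> dict[str, list[MiRNALocus]]:
    out: dict[str, list[MiRNALocus]] = {}
    for loc in loci:
        out.setdefault(loc.mimat_id, []).append(loc)
    return out


def count_chromosome_pairs(
    summary: CorrelationSummary, loci: list[MiRNALocus]
) -> pd.DataFrame:
    """Significant-pair counts per unordered chromosome pair.

    A significant miRNA pair contributes one count to every chromosome-pair
    combination of its loci (duplicated loci count once per combination).
    Unannotated miRNAs are excluded with a warning.
    """
    by_mimat = _loci_by_mimat(loci)
    ids = list(summary.mask.index)
    missing = [m for m in ids if m not in by_mimat]
    if missing:
        warnings.warn(f"{len(missing)} miRNAs without genomic annotation excluded",
                      stacklevel=2)
    annotated = [m for m in ids if m in by_mimat]
    counts: dict[tuple[str, str], int] = {}
    mask = summary.mask
    for a, b in itertools.combinations(annotated, 2):
        if not bool(mask.loc[a, b]):
            continue
        combos = set()
        for la in by_mimat[a]:
            for lb in by_mimat[b]:
                combos.add(tuple(sorted((la.chromosome, lb.chromosome))))
        for key in combos:
            counts[key] = counts.get(key, 0) + 1
    rows = [(c1, c2, n) for (c1, c2), n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["chrom_a", "chrom_b", "n_significant"])


def cross_chromosome_enrichment(
    summary_exposed: CorrelationSummary,
    summary_control: CorrelationSummary,
    loci: list[MiRNALocus],
) -> pd.DataFrame:
    """Fold change (exposed / control) of normalized cross-chromosome
    significant-correlation counts.

    Counts for each unordered chromosome pair (c1 ≠ c2) are normalized by
    the product of the numbers of expressed miRNAs located on c1 and c2;
    division by a zero control count flags the ratio as infinite.
    """
    by_mimat = _loci_by_mimat(loci)
    ids = [m for m in summary_exposed.mask.index if m in by_mimat]
    n_on: dict[str, int] = {}
    for m in ids:
        for chrom in {l.chromosome for l in by_mimat[m]}:
            n_on[chrom] = n_on.get(chrom, 0) + 1

    ce = count_chromosome_pairs(summary_exposed, loci)
    cc = count_chromosome_pairs(summary_control, loci)
    ce = ce[ce.chrom_a != ce.chrom_b].set_index(["chrom_a", "chrom_b"])["n_significant"]
    cc = cc[cc.chrom_a != cc.chrom_b].set_index(["chrom_a", "chrom_b"])["n_significant"]
    pairs = sorted(set(ce.index) | set(cc.index))
    rows = []
    for c1, c2 in pairs:
        denom = n_on.get(c1, 0) * n_on.get(c2, 0)
        ne = ce.get((c1, c2), 0) / denom if denom else np.nan
        nc = cc.get((c1, c2), 0) / denom if denom else np.nan
        if nc == 0:
            fold, inf = (np.nan, False) if ne == 0 else (np.inf, True)
        else:
            fold, inf = ne / nc, False
        rows.append((c1, c2, ce.get((c1, c2), 0), cc.get((c1, c2), 0), ne, nc, fold, inf))
    return pd.DataFrame(
        rows,
        columns=["chrom_a", "chrom_b", "n_exposed", "n_control",
                 "norm_exposed", "norm_control", "fold_change", "infinite"],
    )


def within_cross_partition(summary: CorrelationSummary, loci: list[MiRNALocus]) -> dict:
    """Partition significant pairs into within- and cross-chromosome counts.

    A pair is 'within' when its locus sets share at least one chromosome,
    'cross' otherwise, so within + cross equals the annotated total exactly.
    """
    by_mimat = _loci_by_mimat(loci)
    ids = [m for m in summary.mask.index if m in by_mimat]
    within = cross = 0
    mask = summary.mask
    for a, b in itertools.combinations(ids, 2):
        if not bool(mask.loc[a, b]):
            continue
        chroms_a = {l.chromosome for l in by_mimat[a]}
        chroms_b = {l.chromosome for l in by_mimat[b]}
        if chroms_a & chroms_b:
            within += 1
        else:
            cross += 1
    total = int(
        mask.loc[ids, ids].to_numpy()[np.triu_indices(len(ids), k=1)].sum()
    )
    return {"within": within, "cross": cross, "total": total}
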