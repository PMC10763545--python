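"""Single-marker QTL scan for a binary trait in an F1 outcross.

Genotypes are coded by parental haplotype: maternal markers segregate
h1/h2, paternal markers h3/h4, and "integrated" markers (parental markers
merged at identical physical positions) take the four allele combinations
h1h3, h1h4, h2h3, h2h4.  At each marker an additive linear model is fit by
least squares — the 0/1 phenotype regressed on a maternal indicator
(h2 vs h1) and/or a paternal indicator (h4 vs h3) — and the −log10 of the
model F-test p-value is reported.  Genome-wide significance is assessed by
permuting the phenotype vector and taking the (1 − α) quantile of the
per-permutation maximum statistic.

For a recessive trait carried by the h1h3 combination, recombinant
individuals with a single unambiguous breakpoint on the trait chromosome
delimit the candidate interval: a mutant must carry the causal locus
inside its h1h3 segment, a wild-type individual excludes its h1h3 segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "F1Population",
    "ScanResult",
    "single_marker_scan",
    "permutation_threshold",
    "genotype_phenotype_table",
    "curate_recessive_conflicts",
    "recombinant_interval",
]

MATERNAL_CODES = ("h1", "h2")
PATERNAL_CODES = ("h3", "h4")
INTEGRATED_CODES = ("h1h3", "h1h4", "h2h3", "h2h4")
ORIGINS = ("maternal", "paternal", "integrated")
NEGLOG10_CAP = 300.0


@dataclass
class F1Population:
    """Marker map plus genotype matrix of an F1 outcross population.

    ``markers`` is indexed by marker id with columns ``chrom``, ``pos_bp``
    (1-based) and ``origin``; ``genotypes`` is individuals × markers with
    string codes (NaN for missing).
    """

    markers: pd.DataFrame
    genotypes: pd.DataFrame

    def __post_init__(self) -> None:
        missing_cols = {"chrom", "pos_bp", "origin"} - set(self.markers.columns)
        if missing_cols:
            raise ValueError(f"markers table lacks columns: {sorted(missing_cols)}")
        if self.markers.index.has_duplicates:
            dup = self.markers.index[self.markers.index.duplicated()][0]
            raise ValueError(f"duplicated marker id: {dup!r}")
        if not self.markers.index.equals(pd.Index(self.genotypes.columns)):
            raise ValueError("genotype columns must match the marker table index")
        bad_origin = set(self.markers["origin"]) - set(ORIGINS)
        if bad_origin:
            raise ValueError(f"unknown marker origins: {sorted(bad_origin)}")
        if (self.markers["pos_bp"] < 0).any():
            raise ValueError("marker positions must be non-negative")
        valid = {
            "maternal": set(MATERNAL_CODES),
            "paternal": set(PATERNAL_CODES),
            "integrated": set(INTEGRATED_CODES),
        }
        for marker, origin in self.markers["origin"].items():
            col = self.genotypes[marker].dropna()
            bad = set(col) - valid[origin]
            if bad:
                ind = col[col.isin(bad)].index[0]
                raise ValueError(
                    f"invalid genotype code {sorted(bad)[0]!r} at marker {marker!r}, individual {ind!r}"
                )

    @property
    def individuals(self) -> pd.Index:
        return self.genotypes.index


@dataclass
class ScanResult:
    """Per-marker scan statistics, with an optional permutation threshold."""

    table: pd.DataFrame  # columns: chrom, pos_bp, neglog10p
    threshold: float | None = None

    def with_threshold(self, threshold: float) -> "ScanResult":
        table = self.table.copy()
        table["significant"] = table["neglog10p"] > threshold
        return ScanResult(table=table, threshold=threshold)

    @property
    def peak_marker(self) -> str:
        return str(self.table["neglog10p"].idxmax())


def _indicator_columns(codes: pd.Series, origin: str) -> np.ndarray:
    """Additive design columns (without intercept) for one marker."""
    if origin == "maternal":
        return (codes.to_numpy() == "h2").astype(float)[:, None]
    if origin == "paternal":
        return (codes.to_numpy() == "h4").astype(float)[:, None]
    arr = codes.to_numpy()
    mat = np.array([c[:2] == "h2" for c in arr], dtype=float)
    pat = np.array([c[2:] == "h4" for c in arr], dtype=float)
    return np.column_stack([mat, pat])


def _prepare_designs(pop: F1Population, phen: pd.Series):
    """Per-marker (row-index, orthonormal design basis, df1, df2) tuples.

    The F statistic of the least-squares fit only needs the orthonormal
    basis Q of the centred design: explained SS = ||Qᵀ y_c||².  Markers
    with fewer than two observed genotype classes are skipped (None).
    """
    phen = phen.dropna()
    y_index = phen.index
    prepared = {}
    for marker in pop.markers.index:
        origin = pop.markers.at[marker, "origin"]
        codes = pop.genotypes[marker].reindex(y_index).dropna()
        if codes.empty:
            prepared[marker] = None
            continue
        if codes.nunique() < 2:
            prepared[marker] = None
            continue
        X = _indicator_columns(codes, origin)
        Xc = X - X.mean(axis=0)
        # Drop constant indicator columns (e.g. an integrated marker where
        # only the maternal side segregates in the observed subset).
        keep = Xc.std(axis=0) > 0
        Xc = Xc[:, keep]
        if Xc.shape[1] == 0:
            prepared[marker] = None
            continue
        Q, R = np.linalg.qr(Xc)
        rank = int(np.sum(np.abs(np.diag(R)) > 1e-10))
        Q = Q[:, :rank]
        df1 = rank
        df2 = len(codes) - rank - 1
        if df2 < 1:
            prepared[marker] = None
            continue
        row_pos = y_index.get_indexer(codes.index)
        prepared[marker] = (row_pos, Q, df1, df2)
    return phen, prepared


def _neglog10_f(ess: np.ndarray, rss: np.ndarray, df1: int, df2: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ess / df1) / (rss / df2)
    logp = stats.f.logsf(F, df1, df2) / np.log(10.0)
    out = np.minimum(-logp, NEGLOG10_CAP)
    return np.where(np.isfinite(out), out, NEGLOG10_CAP)


def single_marker_scan(pop: F1Population, phen: pd.Series) -> ScanResult:
    """Fit the additive model at every marker and report −log10 p.

    ``phen`` is a binary (0/1) series indexed by individual; NaN entries
    (unclassified individuals) are dropped.  Raises on a constant
    phenotype.  Markers that cannot be tested are reported as NaN.
    """
    phen_obs, prepared = _prepare_designs(pop, phen)
    if phen_obs.nunique() < 2:
        raise ValueError("phenotype is constant; both classes must be present")
    y = phen_obs.to_numpy(dtype=float)
    out = []
    for marker in pop.markers.index:
        prep = prepared[marker]
        if prep is None:
            out.append(np.nan)
            continue
        row_pos, Q, df1, df2 = prep
        yc = y[row_pos]
        yc = yc - yc.mean()
        tss = float(yc @ yc)
        proj = Q.T @ yc
        ess = float(proj @ proj)
        rss = max(tss - ess, 0.0)
        out.append(float(_neglog10_f(np.array(ess), np.array(rss), df1, df2)))
    table = pop.markers[["chrom", "pos_bp"]].copy()
    table["neglog10p"] = out
    return ScanResult(table=table)


def permutation_threshold(
    pop: F1Population,
    phen: pd.Series,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Genome-wide significance threshold by phenotype permutation.

    The phenotype vector is permuted as a whole ``n_perm`` times; the
    threshold is the (1 − α) quantile of the per-permutation maximum
    −log10 p across markers.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; thresholds will be unstable", stacklevel=2)
    if rng is None:
        rng = np.random.default_rng(seed)
    phen_obs, prepared = _prepare_designs(pop, phen)
    if phen_obs.nunique() < 2:
        raise ValueError("phenotype is constant; both classes must be present")
    y = phen_obs.to_numpy(dtype=float)
    n = len(y)
    Y = np.empty((n, n_perm))
    for j in range(n_perm):
        Y[:, j] = y[rng.permutation(n)]
    max_stat = np.zeros(n_perm)
    for marker in pop.markers.index:
        prep = prepared[marker]
        if prep is None:
            continue
        row_pos, Q, df1, df2 = prep
        Ym = Y[row_pos]
        Ym = Ym - Ym.mean(axis=0)
        tss = np.sum(Ym * Ym, axis=0)
        proj = Q.T @ Ym
        ess = np.sum(proj * proj, axis=0)
        rss = np.maximum(tss - ess, 0.0)
        stat = _neglog10_f(ess, rss, df1, df2)
        np.maximum(max_stat, stat, out=max_stat)
    return float(np.quantile(max_stat, 1.0 - alpha))


def genotype_phenotype_table(pop: F1Population, marker: str, phen: pd.Series) -> pd.DataFrame:
    """Contingency counts of allele combination × phenotype call at a marker.

    Rows are the four integrated allele combinations; columns are
    ``wild_type``, ``mutant`` and ``unclassified`` (NaN phenotypes).
    """
    if pop.markers.at[marker, "origin"] != "integrated":
        raise ValueError(f"marker {marker!r} has no integrated allele combinations")
    codes = pop.genotypes[marker]
    phen = phen.reindex(codes.index)
    call = pd.Series("unclassified", index=codes.index, name="phenotype")
    call[phen == 0] = "wild_type"
    call[phen == 1] = "mutant"
    tab = pd.crosstab(codes, call)
    tab = tab.reindex(index=list(INTEGRATED_CODES), columns=["wild_type", "mutant", "unclassified"], fill_value=0)
    tab.index.name = "genotype"
    return tab


def curate_recessive_conflicts(
    pop: F1Population,
    phen: pd.Series,
    marker: str,
    mutant_class: str = "h1h3",
) -> pd.Series:
    """Blank phenotype calls that contradict recessive inheritance at a marker.

    At a marker in (near-)perfect linkage with the causal locus, a
    classified phenotype that disagrees with the recessive model — a
    mutant call without the ``mutant_class`` combination, or a wild-type
    call carrying it — is a misclassification and would poison the
    recombinant analysis.  Such calls are set to NaN (unclassified).
    """
    codes = pop.genotypes[marker].reindex(phen.index)
    expected = (codes == mutant_class).astype(float)
    out = phen.copy()
    conflict = phen.notna() & codes.notna() & (phen != expected)
    out[conflict] = np.nan
    return out


def _runs(values: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) index pairs of maximal constant runs (end exclusive)."""
    runs = []
    start = 0
    for i in range(1, len(values)):
        if values[i] != values[i - 1]:
            runs.append((start, i))
            start = i
    runs.append((start, len(values)))
    return runs


def recombinant_interval(
    pop: F1Population,
    phen: pd.Series,
    chrom: str,
    mutant_class: str = "h1h3",
) -> tuple[int, int]:
    """Delimit the causal interval from single-breakpoint recombinants.

    Uses integrated markers on ``chrom``.  Individuals with exactly one
    breakpoint separating a ``mutant_class`` segment from another
    combination are informative: mutants confine the locus to their
    mutant-class segment, wild types exclude theirs.  Returns the
    intersection of the per-individual constraints as a half-open
    ``[start, end)`` interval in bp (1-based start).  With no informative
    recombinants the whole chromosome is returned with a warning.
    """
    sel = (pop.markers["chrom"] == chrom) & (pop.markers["origin"] == "integrated")
    markers = pop.markers[sel].sort_values("pos_bp")
    if markers.empty:
        raise ValueError(f"no integrated markers on chromosome {chrom!r}")
    pos = markers["pos_bp"].to_numpy()
    lo, hi = 0, int(pos[-1]) + 1
    informative = 0
    for ind, p in phen.dropna().items():
        codes = pop.genotypes.loc[ind, markers.index].dropna()
        if len(codes) < 2:
            continue
        vals = codes.to_numpy()
        obs_pos = markers.loc[codes.index, "pos_bp"].to_numpy()
        runs = _runs(vals)
        if len(runs) != 2:
            continue
        run_is_mutant = [vals[s] == mutant_class for s, _ in runs]
        if sum(run_is_mutant) != 1:
            continue
        informative += 1
        breakpoint_bp = int(obs_pos[runs[1][0]])  # first marker of the second run
        mutant_first = run_is_mutant[0]
        if p == 1:  # mutant: locus inside the mutant-class segment
            seg = (lo, breakpoint_bp) if mutant_first else (breakpoint_bp, hi)
        else:  # wild type: locus outside the mutant-class segment
            seg = (breakpoint_bp, hi) if mutant_first else (lo, breakpoint_bp)
        lo, hi = max(lo, seg[0]), min(hi, seg[1])
        if lo >= hi:
            raise ValueError("recombinant constraints are contradictory (empty interval)")
    if informative == 0:
        warnings.warn(f"no informative recombinants on {chrom}; returning whole chromosome", stacklevel=2)
    return lo, hi
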