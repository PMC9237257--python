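"""Expression quantification and QC.

FPKM (fragments per kilobase of transcript per million mapped fragments)
normalises a raw fragment count ``C`` for gene length ``L`` (bp) and library
size ``N``::

    FPKM = 1e9 * C / (N * L)

Genes are considered *expressed* in a sample group when their group-mean FPKM
reaches a threshold (1.0 by default); expressed-gene sets per group feed the
four-way co-expression Venn and define the per-contrast analysis universe.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "FpkmMatrix",
    "read_design",
    "validate_design",
    "standard_contrasts",
    "compute_fpkm",
    "expressed_sets",
    "replicate_correlation",
    "coexpression_venn",
    "VennCounts",
]

GENOTYPES = ("transgenic", "progenitor")
SITES = ("saline", "nonsaline")


@dataclass
class CountMatrix:
    """Gene x sample integer count matrix with per-gene lengths.

    Parameters
    ----------
    counts : DataFrame
        Non-negative integer counts, genes in rows, samples in columns.
    lengths : Series
        Effective gene length in bp, indexed like ``counts``.
    library_sizes : Series, optional
        Mapped-fragment total per sample.  Defaults to the column sums of
        ``counts`` (an explicit total may be supplied when counts are a
        filtered subset of the library).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("missing gene length for some genes")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = self.library_sizes.reindex(self.counts.columns)
            if self.library_sizes.isna().any():
                raise ValueError("missing library size for some samples")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @classmethod
    def read_tsv(cls, path) -> "CountMatrix":
        """Read ``counts.tsv`` (gene_id, length, one column per sample)."""
        df = pd.read_csv(path, sep="\t", comment="#", index_col="gene_id")
        lengths = df.pop("length")
        return cls(counts=df.astype(np.int64), lengths=lengths.astype(float))

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.lengths.astype(int))
        out.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class FpkmMatrix:
    """FPKM values with a provenance link to the source counts."""

    values: pd.DataFrame
    source: CountMatrix | None = field(default=None, repr=False)
    metadata: dict = field(default_factory=dict)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index


def compute_fpkm(counts: CountMatrix) -> FpkmMatrix:
    """FPKM_gs = 1e9 * C_gs / (N_s * L_g).

    A zero count maps to zero FPKM, and scaling one sample's counts together
    with its library size leaves that sample's FPKM unchanged.
    """
    c = counts.counts.to_numpy(dtype=float)
    n = counts.library_sizes.to_numpy(dtype=float)[np.newaxis, :]
    length = counts.lengths.to_numpy(dtype=float)[:, np.newaxis]
    fpkm = 1e9 * c / (n * length)
    values = pd.DataFrame(fpkm, index=counts.counts.index, columns=counts.counts.columns)
    return FpkmMatrix(values=values, source=counts)


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------

def validate_design(design: pd.DataFrame, min_replicates: int = 2) -> pd.DataFrame:
    """Check the 2x2 factorial sample sheet and derive group labels.

    ``design`` needs columns sample_id, genotype, site, replicate.  Group
    codes follow the saline/nonsaline x transgenic/progenitor convention
    (DA, DB, QA, QB: D = saline site, Q = nonsaline site, A = transgenic,
    B = progenitor).
    """
    required = {"sample_id", "genotype", "site", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design is missing columns: {sorted(missing)}")
    design = design.copy()
    bad_geno = set(design["genotype"]) - set(GENOTYPES)
    if bad_geno:
        raise ValueError(f"unknown genotype labels: {sorted(bad_geno)}")
    bad_site = set(design["site"]) - set(SITES)
    if bad_site:
        raise ValueError(f"unknown site labels: {sorted(bad_site)}")
    if "group" not in design.columns:
        site_code = design["site"].map({"saline": "D", "nonsaline": "Q"})
        geno_code = design["genotype"].map({"transgenic": "A", "progenitor": "B"})
        design["group"] = site_code + geno_code
    sizes = design.groupby("group").size()
    if len(sizes) != 4:
        raise ValueError(f"expected a complete 2x2 design, found groups {list(sizes.index)}")
    if (sizes < min_replicates).any():
        raise ValueError(f"every group needs >= {min_replicates} replicates, got\n{sizes}")
    return design.set_index("sample_id", drop=False)


def read_design(path, min_replicates: int = 2) -> pd.DataFrame:
    return validate_design(pd.read_csv(path, sep="\t", comment="#"), min_replicates)


def standard_contrasts(design: pd.DataFrame) -> dict[str, tuple[str, str]]:
    """The four paired contrasts of the 2x2 design.

    Two genotype contrasts (transgenic vs progenitor within each site) and
    two site contrasts (saline vs nonsaline within each genotype); contrast
    ids are ``"<groupA>-vs-<groupB>"``.
    """
    group_of = {}
    for _, row in design.iterrows():
        group_of[(row["site"], row["genotype"])] = row["group"]
    contrasts = {}
    for site in SITES:
        a, b = group_of[(site, "transgenic")], group_of[(site, "progenitor")]
        contrasts[f"{a}-vs-{b}"] = (a, b)
    for geno in GENOTYPES:
        a, b = group_of[("saline", geno)], group_of[("nonsaline", geno)]
        contrasts[f"{a}-vs-{b}"] = (a, b)
    return contrasts


def _group_samples(design: pd.DataFrame) -> dict[str, list[str]]:
    return {g: list(sub["sample_id"]) for g, sub in design.groupby("group")}


def group_mean_fpkm(fpkm: FpkmMatrix, design: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean FPKM (columns = group labels)."""
    groups = _group_samples(design)
    return pd.DataFrame(
        {g: fpkm.values[samples].mean(axis=1) for g, samples in groups.items()}
    )


# ---------------------------------------------------------------------------
# expressed-gene sets, QC, Venn
# ---------------------------------------------------------------------------

def expressed_sets(
    fpkm: FpkmMatrix,
    design: pd.DataFrame,
    threshold: float = 1.0,
    mode: str = "group-mean",
) -> dict[str, set[str]]:
    """Expressed genes per group: group-mean FPKM >= threshold (inclusive).

    ``mode="any-replicate"`` instead requires any single replicate to reach
    the threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if mode not in ("group-mean", "any-replicate"):
        raise ValueError(f"unknown expressed-set mode {mode!r}")
    groups = _group_samples(design)
    out: dict[str, set[str]] = {}
    for g, samples in groups.items():
        sub = fpkm.values[samples]
        if mode == "group-mean":
            mask = sub.mean(axis=1) >= threshold
        else:
            mask = (sub >= threshold).any(axis=1)
        out[g] = set(sub.index[mask])
    return out


def replicate_correlation(fpkm: FpkmMatrix, design: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of log10(FPKM + 1) for every sample pair.

    Constant columns have undefined correlation; these are reported as NaN
    with a warning.  The log transform is recorded in the matrix attrs.
    """
    logged = np.log10(fpkm.values[design["sample_id"]] + 1.0)
    constant = logged.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            "correlation undefined for constant sample(s): "
            + ", ".join(logged.columns[constant]),
            stacklevel=2,
        )
    corr = logged.corr(method="pearson")
    corr.attrs["transform"] = "log10(FPKM+1)"
    return corr


@dataclass
class VennCounts:
    """Region counts for the four-group expressed-gene Venn.

    ``regions`` maps each of the 15 non-empty membership signatures (a
    frozenset of group labels) to the number of genes exactly in those
    groups; disjoint regions sum to the union size.  ``pairwise`` holds
    plain pairwise intersection sizes.
    """

    regions: dict[frozenset, int]
    pairwise: dict[frozenset, int]
    union_size: int
    set_names: tuple[str, ...]

    def region(self, *names: str) -> int:
        return self.regions[frozenset(names)]

    def intersection(self, a: str, b: str) -> int:
        return self.pairwise[frozenset((a, b))]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": "&".join(sorted(k)), "n_groups": len(k), "count": v}
            for k, v in sorted(self.regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
        ]
        return pd.DataFrame(rows)


def coexpression_venn(sets: Mapping[str, Iterable[str]]) -> VennCounts:
    """Exclusive region counts and pairwise intersections for named sets."""
    names = tuple(sets)
    as_sets = {k: set(v) for k, v in sets.items()}
    universe = set().union(*as_sets.values()) if as_sets else set()
    regions: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            regions[frozenset(combo)] = 0
    for gene in universe:
        membership = frozenset(k for k, s in as_sets.items() if gene in s)
        regions[membership] += 1
    pairwise = {
        frozenset((a, b)): len(as_sets[a] & as_sets[b])
        for a, b in itertools.combinations(names, 2)
    }
    return VennCounts(
        regions=regions, pairwise=pairwise, union_size=len(universe), set_names=names
    )
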