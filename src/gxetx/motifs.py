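"""Promoter extraction and degenerate cis-element scanning.

The scan targets the core boxes bound by AP2/ERF-type transcription factors
such as the jasmonate/ethylene-responsive factor introduced into the
transgenic line:

* GCC-box — ``GCCGCC`` (ethylene-responsive element)
* DREB    — ``CCGAC``  (dehydration-responsive element core)
* ABRE    — ``YACGTGKC`` (ABA-responsive element, (C/T)ACGTG(T/G)C)

Patterns use the IUPAC ambiguity alphabet; an ``N`` in the *sequence*
matches nothing.  By default both strands of the promoter window are
scanned and reverse-strand hits are reported in forward-strand
coordinates (1-based, closed intervals).
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._formatting import format_count_pct, pct_round_half_up
from .degtest import DegSet

__all__ = [
    "IUPAC",
    "CisElementDef",
    "DEFAULT_ELEMENTS",
    "GeneModel",
    "expand_iupac",
    "reverse_complement",
    "extract_promoter",
    "scan_elements",
    "scan_promoters",
    "summarize_cis_elements",
]

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class CisElementDef:
    """A named IUPAC core pattern."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty pattern")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {sorted(bad)} in pattern {self.pattern!r}")


DEFAULT_ELEMENTS: tuple[CisElementDef, ...] = (
    CisElementDef("GCC-box", "GCCGCC"),
    CisElementDef("ABRE", "YACGTGKC"),
    CisElementDef("DREB", "CCGAC"),
)


def expand_iupac(pattern: str) -> list[str]:
    """All concrete A/C/G/T strings matching an IUPAC pattern."""
    choices = [IUPAC[c] for c in pattern.upper()]
    return ["".join(p) for p in itertools.product(*choices)]


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _pattern_regex(pattern: str) -> re.Pattern:
    # lookahead so overlapping matches are all reported; character classes
    # contain only ACGT, so N in the subject never matches
    body = "".join(
        c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in pattern.upper()
    )
    return re.compile(f"(?=({body}))")


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: contig, strand, and 1-based TSS on the forward strand."""

    gene_id: str
    contig: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 1:
            raise ValueError("TSS must be a positive 1-based coordinate")


def extract_promoter(
    model: GeneModel, sequences: Mapping[str, str], length: int = 2000
) -> str:
    """Strand-aware promoter window upstream of the TSS.

    Forward strand: bases [TSS-length, TSS-1] of the contig.  Reverse
    strand: the reverse complement of [TSS+1, TSS+length].  Windows are
    truncated at contig boundaries with a warning.
    """
    if length <= 0:
        raise ValueError("promoter length must be positive")
    if model.contig not in sequences:
        raise KeyError(f"contig {model.contig!r} not in sequence source")
    contig = str(sequences[model.contig]).upper()
    if model.tss > len(contig):
        raise ValueError(
            f"TSS {model.tss} beyond end of contig {model.contig!r} (len {len(contig)})"
        )
    if model.strand == "+":
        start = model.tss - length  # 1-based
        if start < 1:
            warnings.warn(
                f"promoter of {model.gene_id} truncated at contig start "
                f"({model.tss - 1} of {length} bp)",
                stacklevel=2,
            )
            start = 1
        return contig[start - 1 : model.tss - 1]
    end = model.tss + length
    if end > len(contig):
        warnings.warn(
            f"promoter of {model.gene_id} truncated at contig end "
            f"({len(contig) - model.tss} of {length} bp)",
            stacklevel=2,
        )
        end = len(contig)
    return reverse_complement(contig[model.tss : end])


def scan_elements(
    sequence: str,
    elements: Sequence[CisElementDef] = DEFAULT_ELEMENTS,
    both_strands: bool = True,
) -> pd.DataFrame:
    """All exact IUPAC matches of each element in one sequence.

    Returns a frame with columns element, start, end (1-based closed,
    forward coordinates), strand, match (the matched forward-strand
    substring for '+' hits, the element-orientation sequence for '-' hits).
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters {sorted(bad)}")
    rows = []
    n = len(seq)
    for element in elements:
        regex = _pattern_regex(element.pattern)
        w = len(element.pattern)
        for m in regex.finditer(seq):
            rows.append(
                {
                    "element": element.name,
                    "start": m.start() + 1,
                    "end": m.start() + w,
                    "strand": "+",
                    "match": m.group(1),
                }
            )
        if both_strands:
            rc = reverse_complement(seq)
            for m in regex.finditer(rc):
                # position i (0-based) in rc covers forward bases
                # [n - i - w + 1, n - i] in 1-based closed coordinates
                rows.append(
                    {
                        "element": element.name,
                        "start": n - m.start() - w + 1,
                        "end": n - m.start(),
                        "strand": "-",
                        "match": m.group(1),
                    }
                )
    frame = pd.DataFrame(rows, columns=["element", "start", "end", "strand", "match"])
    return frame.sort_values(["element", "start", "strand"], ignore_index=True)


def scan_promoters(
    promoters: Mapping[str, str],
    elements: Sequence[CisElementDef] = DEFAULT_ELEMENTS,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Scan many promoters; adds a gene_id column."""
    frames = []
    for gene_id, seq in promoters.items():
        hits = scan_elements(seq, elements, both_strands)
        if len(hits):
            hits.insert(0, "gene_id", gene_id)
            frames.append(hits)
    if not frames:
        return pd.DataFrame(
            columns=["gene_id", "element", "start", "end", "strand", "match"]
        )
    return pd.concat(frames, ignore_index=True)


def summarize_cis_elements(
    degs: DegSet,
    scans: pd.DataFrame,
    elements: Sequence[CisElementDef] = DEFAULT_ELEMENTS,
    label: str = "",
) -> pd.DataFrame:
    """Cis-element summary per DEG direction (report-table shape).

    One row per direction with the DEG total, genes carrying >= 1 element,
    per-element gene counts, and genes with exactly 2 / with 3 distinct
    element types, each with a round-half-up percentage of the direction
    total.  A DEG without a promoter scan record counts as element-absent
    (with a warning).
    """
    scanned_genes = set(scans["gene_id"]) if len(scans) else set()
    missing = degs.genes - scanned_genes
    # genes whose promoters were scanned but had no hits are simply absent
    # from `scans`; only warn when the caller supplied no record at all
    if missing and "scanned_gene_ids" in scans.attrs:
        truly_missing = missing - set(scans.attrs["scanned_gene_ids"])
        if truly_missing:
            warnings.warn(
                f"{len(truly_missing)} DEG(s) without promoter records counted "
                "as element-absent",
                stacklevel=2,
            )
    per_gene = (
        scans.groupby("gene_id")["element"].agg(lambda s: frozenset(s))
        if len(scans)
        else pd.Series(dtype=object)
    )
    rows = []
    for direction, genes in (("up", degs.up), ("down", degs.down)):
        total = len(genes)
        kinds = {g: per_gene.get(g, frozenset()) for g in genes}
        n_with = sum(1 for k in kinds.values() if k)
        row: dict = {
            "label": label,
            "direction": direction,
            "total_degs": total,
            "with_element": n_with,
            "with_element_pct": pct_round_half_up(n_with, total) if total else 0.0,
            "with_element_fmt": format_count_pct(n_with, total) if total else "0 (0.00%)",
        }
        for element in elements:
            n_el = sum(1 for k in kinds.values() if element.name in k)
            key = element.name.lower().replace("-", "_")
            row[key] = n_el
            row[f"{key}_pct"] = pct_round_half_up(n_el, total) if total else 0.0
        for label_n, count_n in (("two_elements", 2), ("three_elements", 3)):
            n_k = sum(1 for k in kinds.values() if len(k) == count_n)
            row[label_n] = n_k
            row[f"{label_n}_pct"] = pct_round_half_up(n_k, total) if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
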