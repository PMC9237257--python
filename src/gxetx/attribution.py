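"""Directional attribution of differential expression to its source.

With a 2x2 genotype x environment design and its four paired contrasts,
a DEG shared by the two *genotype* contrasts (transgenic vs progenitor at
each site) with the same fold-change sign is attributed to the transgene;
shared with opposite signs it reflects a genotype x environment interaction.
Symmetrically, a DEG shared by the two *site* contrasts with equal signs is
attributed to the environment, with opposite signs to the interaction.  Sign
agreement, not magnitude, defines "same expression pattern", and a gene may
legitimately hold a class in both pairings (the two pairings are reported
separately).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .degtest import DegSet

__all__ = ["EffectClassification", "classify_effects", "attribution_counts"]

CLASSES = ("transgene", "environment", "interaction_genotype", "interaction_environment")


@dataclass
class EffectClassification:
    """Per-gene effect attribution.

    ``table`` columns: gene_id, pairing ("genotype" or "environment"),
    klass (one of the four class labels), dir1/dir2 (fold-change signs in
    the first/second contrast of the pairing).
    """

    table: pd.DataFrame
    contrast_pairs: dict[str, tuple[str, str]] = field(default_factory=dict)

    def genes(self, klass: str) -> set[str]:
        if klass not in CLASSES:
            raise ValueError(f"unknown class {klass!r}")
        return set(self.table.loc[self.table["klass"] == klass, "gene_id"])

    def to_tsv(self, path, lfc: dict[str, pd.Series] | None = None) -> None:
        out = self.table.copy()
        if lfc is not None:
            out["lfc1"] = [
                lfc[self.contrast_pairs[row.pairing][0]].get(row.gene_id)
                for row in out.itertuples()
            ]
            out["lfc2"] = [
                lfc[self.contrast_pairs[row.pairing][1]].get(row.gene_id)
                for row in out.itertuples()
            ]
        out.to_csv(path, sep="\t", index=False)


def _classify_pair(
    first: DegSet, second: DegSet, pairing: str, same_class: str, opposite_class: str
) -> list[dict]:
    rows = []
    for gene in sorted(first.genes & second.genes):
        d1, d2 = first.directions[gene], second.directions[gene]
        klass = same_class if d1 == d2 else opposite_class
        rows.append(
            {"gene_id": gene, "pairing": pairing, "klass": klass, "dir1": d1, "dir2": d2}
        )
    return rows


def classify_effects(
    deg_genotype_saline: DegSet,
    deg_genotype_nonsaline: DegSet,
    deg_site_transgenic: DegSet,
    deg_site_progenitor: DegSet,
) -> EffectClassification:
    """Classify shared DEGs by directional agreement across paired contrasts.

    Arguments are the DEG sets of, in order: transgenic-vs-progenitor at the
    saline site, the same at the non-saline site, saline-vs-nonsaline in the
    transgenic line, and the same in the progenitor line.
    """
    ids = [
        deg_genotype_saline.contrast_id,
        deg_genotype_nonsaline.contrast_id,
        deg_site_transgenic.contrast_id,
        deg_site_progenitor.contrast_id,
    ]
    if len(set(ids)) != 4:
        raise ValueError(f"the four DEG sets must come from distinct contrasts, got {ids}")
    rows = _classify_pair(
        deg_genotype_saline,
        deg_genotype_nonsaline,
        "genotype",
        "transgene",
        "interaction_genotype",
    )
    rows += _classify_pair(
        deg_site_transgenic,
        deg_site_progenitor,
        "environment",
        "environment",
        "interaction_environment",
    )
    table = pd.DataFrame(rows, columns=["gene_id", "pairing", "klass", "dir1", "dir2"])
    return EffectClassification(
        table=table,
        contrast_pairs={
            "genotype": (ids[0], ids[1]),
            "environment": (ids[2], ids[3]),
        },
    )


def attribution_counts(classification: EffectClassification) -> dict:
    """Totals and up/down splits per class.

    "up"/"down" report genes whose shared direction is +1/-1 in the first
    contrast of the pairing (for same-sign classes both contrasts agree);
    the interaction total pools both pairings.
    """
    t = classification.table
    out: dict = {}
    for klass in CLASSES:
        sub = t[t["klass"] == klass]
        out[klass] = {
            "total": len(sub),
            "up": int((sub["dir1"] == 1).sum()),
            "down": int((sub["dir1"] == -1).sum()),
        }
    out["interaction"] = {
        "total": out["interaction_genotype"]["total"]
        + out["interaction_environment"]["total"]
    }
    return out
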