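"""Functional summaries of non-defense hotspot cargo.

Two readouts: a domain tally over cargo genes that are *not* part of any
called defense system (most hotspot cargo matches no known domain — the
discovery space), and a mobilome classification that buckets genes as
integrative / prophage / conjugative by keyword match on their
major-category annotation, reporting the fraction of loci with no mobile
gene at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .hotspot_mapper import HotspotLocus
from .system_caller import SystemCall

DEFAULT_DOMAIN_EVALUE_MAX = 0.01

# fixed priority when several keywords match one annotation
MOBILOME_KEYWORDS = [
    ("integration", "integrative"),
    ("phage", "prophage"),
    ("conjugation", "conjugative"),
]


@dataclass(frozen=True)
class DomainHit:
    gene_id: str
    domain_id: str
    domain_name: str = ""
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")


@dataclass(frozen=True)
class MobileAnnotation:
    gene_id: str
    major_category: str

    @property
    def mapped_class(self) -> str:
        cat = self.major_category.lower()
        for keyword, klass in MOBILOME_KEYWORDS:
            if keyword in cat:
                return klass
        return "other"


def domain_tally(
    hits: Iterable[DomainHit],
    loci: Sequence[HotspotLocus],
    calls: Sequence[SystemCall],
    evalue_max: float = DEFAULT_DOMAIN_EVALUE_MAX,
) -> pd.DataFrame:
    """Count cargo genes per domain, restricted to non-defense genes.

    Genes belonging to any system call are excluded before tallying; the
    e-value comparison is inclusive (<= cutoff). The returned table also
    carries one ``(no_domain)`` row with the count of non-defense cargo
    genes matching nothing — typically the majority.
    """
    defense_genes = {g for c in calls for g in c.member_gene_ids}
    cargo_genes = {
        g.gene_id for locus in loci for g in locus.cargo_genes
    } - defense_genes
    genes_per_domain: dict[str, set[str]] = {}
    matched: set[str] = set()
    for h in hits:
        if h.gene_id not in cargo_genes or h.evalue > evalue_max:
            continue
        genes_per_domain.setdefault(h.domain_id, set()).add(h.gene_id)
        matched.add(h.gene_id)
    rows = [
        {"domain_id": dom, "n_genes": len(gids),
         "fraction_of_cargo": len(gids) / len(cargo_genes)}
        for dom, gids in sorted(genes_per_domain.items())
    ]
    rows.append(
        {
            "domain_id": "(no_domain)",
            "n_genes": len(cargo_genes) - len(matched),
            "fraction_of_cargo": (
                (len(cargo_genes) - len(matched)) / len(cargo_genes)
                if cargo_genes else 0.0
            ),
        }
    )
    df = pd.DataFrame(rows, columns=["domain_id", "n_genes", "fraction_of_cargo"])
    return df.sort_values(
        ["n_genes", "domain_id"], ascending=[False, True]
    ).reset_index(drop=True)


def mobilome_classify(
    annotations: Iterable[MobileAnnotation],
    loci: Sequence[HotspotLocus],
) -> dict:
    """Classify cargo genes by mobile-element category and summarise.

    Per gene the class is decided by case-insensitive substring match on
    the major-category annotation, in fixed priority order (integration >
    phage > conjugation); per locus, the set of classes present (or
    "none"); overall, the fraction of loci with no mobile gene.
    """
    gene_class = {a.gene_id: a.mapped_class for a in annotations}
    per_locus = []
    n_no_mobile = 0
    for locus in loci:
        classes = sorted(
            {
                gene_class[g.gene_id]
                for g in locus.cargo_genes
                if gene_class.get(g.gene_id, "other") != "other"
            }
        )
        if not classes:
            n_no_mobile += 1
        per_locus.append(
            {
                "hotspot": locus.hotspot_name,
                "genome_id": locus.genome_id,
                "replicon_id": locus.replicon_id,
                "classes": ",".join(classes) if classes else "none",
            }
        )
    return {
        "gene_classes": gene_class,
        "per_locus": pd.DataFrame(
            per_locus, columns=["hotspot", "genome_id", "replicon_id", "classes"]
        ),
        "no_mobile_fraction": n_no_mobile / len(loci) if loci else 0.0,
    }


# ---------------------------------------------------------------------------
# tabular ingestion
# ---------------------------------------------------------------------------

def read_rpsblast_outfmt6(path: str) -> list[DomainHit]:
    """rpsblast tabular (outfmt 6): query = gene, subject = domain model."""
    cols = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols,
                     dtype={"qseqid": str, "sseqid": str})
    return [
        DomainHit(gene_id=r.qseqid, domain_id=r.sseqid, evalue=float(r.evalue))
        for r in df.itertuples(index=False)
    ]


def read_mobile_annotations(path: str) -> list[MobileAnnotation]:
    """mobileOG-style TSV with columns gene_id, major_category."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        MobileAnnotation(gene_id=r.gene_id, major_category=r.major_category)
        for r in df.itertuples(index=False)
    ]


def write_domain_tally(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_mobilome_report(report: dict, path: str) -> None:
    report["per_locus"].to_csv(path, sep="\t", index=False)
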