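"""Bundled reference datasets from the KT2440/RP4 fitness-cost study.

Three small published summary tables ship with the package so the
headline analyses run without any external download:

* whole-genome sequencing coverage per replicon for the ancestral
  KT2440(RP4) strain and twelve evolved/control isolates,
* the 33 differentially transcribed ORFs (27 up, 6 down) found when the
  cost-associated chromosomal sRNA region is overexpressed, with their
  COG codes,
* genome-wide COG category counts for the 5,350 KT2440 ORFs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .coverage import ReplicomCoverage
from .enrichment import CogTally

__all__ = [
    "load_wgs_coverage",
    "load_de_orfs",
    "load_genome_cog_counts",
    "de_cog_tally",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("plasfit.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t")


def load_wgs_coverage() -> list[ReplicomCoverage]:
    """Per-strain replicon coverage for the 13 sequenced isolates."""
    df = _read("wgs_coverage_kt2440_rp4.tsv")
    return [
        ReplicomCoverage(
            strain_id=r.strain_id,
            total_reads=int(r.total_reads),
            reads_chromosome=int(r.reads_chromosome),
            reads_plasmid=int(r.reads_plasmid),
            coverage_chromosome=float(r.coverage_chromosome),
            coverage_plasmid=float(r.coverage_plasmid),
        )
        for r in df.itertuples()
    ]


def load_de_orfs() -> pd.DataFrame:
    """The 33 DE ORFs under sRNA-region overexpression (orf_id, gene_name,
    cog_code, product, direction)."""
    return _read("de_orfs_kt2440_srna_overexpression.tsv")


def load_genome_cog_counts() -> dict[str, int]:
    """Genome-wide ORF count per COG category (the "–" key collects
    unassigned ORFs); values sum to 5,350."""
    df = _read("cog_genome_kt2440.tsv")
    return dict(zip(df.cog_code, df.genome_count.astype(int)))


def de_cog_tally() -> CogTally:
    """2x2 enrichment counts: the bundled DE set against the genome.

    Built directly from the per-category counts rather than a per-ORF
    genome annotation (which the summary tables do not resolve): k comes
    from the DE table's COG codes, K from the genome category counts.
    """
    de = load_de_orfs()
    genome = load_genome_cog_counts()
    k_counts = de.cog_code.value_counts().to_dict()
    per_code = {
        code: (int(k_counts.get(code, 0)), int(K)) for code, K in genome.items()
    }
    return CogTally(per_code, n=len(de), N=sum(genome.values()))


def _consistency_check() -> None:  # pragma: no cover - debugging helper
    tally = de_cog_tally()
    assert sum(k for k, _ in tally.per_code.values()) == tally.n
    assert sum(K for _, K in tally.per_code.values()) == tally.N
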