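"""Microarray probe reannotation to lncRNA transcripts.

Array platforms predate current noncoding annotation, so probes designed
against older transcript models are re-mapped here against a transcript
FASTA with biotype metadata.  Matching is exact and full-length (adequate
for 25-mer probes), on both strands, via a k-mer substring index.  A gene is
accepted as a measurable lncRNA when (a) at least ``min_probes`` distinct
probes match it, (b) every such match is perfect (exact full-length), and
(c) specific (all of a probe's hits fall in that one gene), and (d) its
biotype is on the lncRNA whitelist.  Expression of an accepted gene is the
arithmetic mean of its supporting probes' rows.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LNCRNA_BIOTYPES",
    "TranscriptRecord",
    "Hit",
    "ProbeMapping",
    "SubstringIndex",
    "index_transcripts",
    "map_probes",
    "filter_mappings",
    "aggregate_to_lncrna",
]

#: gene biotypes treated as lncRNA
LNCRNA_BIOTYPES = (
    "lincRNA",
    "bidirectional_promoter_lncRNA",
    "macro_lncRNA",
    "antisense",
    "processed_transcript",
    "TEC",
    "3prime_overlapping_ncRNA",
    "sense_intronic",
    "non_coding",
    "sense_overlapping",
)

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptRecord:
    transcript_id: str
    gene_id: str
    gene_symbol: str
    biotype: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.transcript_id}")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(
                f"transcript {self.transcript_id} has invalid characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class Hit:
    transcript_id: str
    gene_id: str
    offset: int  # 0-based, forward-strand transcript coordinate
    strand: str  # "+" or "-"


@dataclass
class ProbeMapping:
    probe_id: str
    probeset_id: str
    hits: list[Hit] = field(default_factory=list)

    @property
    def is_perfect(self) -> bool:
        """True iff the probe has at least one exact full-length hit."""
        return len(self.hits) > 0

    @property
    def is_specific(self) -> bool:
        """True iff all hits fall within exactly one gene."""
        return len({h.gene_id for h in self.hits}) == 1

    @property
    def gene_ids(self) -> set[str]:
        return {h.gene_id for h in self.hits}


class SubstringIndex:
    """Exact-match index of all fixed-length transcript substrings.

    Windows containing N are not indexed.  Lookups check the probe and its
    reverse complement; reverse-complement hits carry strand "-" with the
    offset of the forward-strand window.
    """

    def __init__(self, records: list[TranscriptRecord], probe_length: int):
        if probe_length < 4:
            raise ValueError("probe_length must be >= 4")
        self.probe_length = probe_length
        self.records = list(records)
        self._windows: dict[str, list[tuple[str, str, int]]] = defaultdict(list)
        for rec in self.records:
            seq = rec.sequence
            for off in range(len(seq) - probe_length + 1):
                window = seq[off : off + probe_length]
                if "N" in window:
                    continue
                self._windows[window].append((rec.transcript_id, rec.gene_id, off))

    def lookup(self, probe: str) -> list[Hit]:
        if len(probe) != self.probe_length:
            raise ValueError(
                f"probe length {len(probe)} != index length {self.probe_length}"
            )
        hits = [
            Hit(tid, gid, off, "+") for tid, gid, off in self._windows.get(probe, ())
        ]
        rc = reverse_complement(probe)
        if rc != probe:
            hits += [
                Hit(tid, gid, off, "-") for tid, gid, off in self._windows.get(rc, ())
            ]
        return hits


def index_transcripts(
    records: list[TranscriptRecord], probe_length: int
) -> SubstringIndex:
    """Build the exact-substring index used by :func:`map_probes`."""
    return SubstringIndex(records, probe_length)


def map_probes(probes: pd.DataFrame, index: SubstringIndex) -> list[ProbeMapping]:
    """Map every probe (columns ``probe_id, probeset_id, sequence``) exactly.

    Probes with zero hits are retained with an empty hit list.  A probe whose
    length differs from the index raises, naming the probe.
    """
    mappings = []
    for row in probes.itertuples(index=False):
        if len(row.sequence) != index.probe_length:
            raise ValueError(
                f"probe {row.probe_id!r} has length {len(row.sequence)}; "
                f"index expects {index.probe_length}"
            )
        mappings.append(
            ProbeMapping(row.probe_id, row.probeset_id, index.lookup(row.sequence))
        )
    return mappings


def filter_mappings(
    mappings: list[ProbeMapping],
    biotypes: pd.DataFrame,
    whitelist: tuple[str, ...] = LNCRNA_BIOTYPES,
    min_probes: int = 4,
) -> pd.DataFrame:
    """Accepted lncRNA genes with their supporting probes.

    ``biotypes`` maps gene annotation (columns ``gene_id, gene_symbol,
    biotype``; one row per gene or per transcript).  A gene is retained iff
    it has >= ``min_probes`` distinct perfectly-and-specifically matching
    probes and a whitelisted biotype.  Returns a DataFrame with columns
    ``gene_id, gene_symbol, biotype, probe_ids, n_probes`` sorted by gene_id.
    """
    gene_meta = (
        biotypes[["gene_id", "gene_symbol", "biotype"]]
        .drop_duplicates("gene_id")
        .set_index("gene_id")
    )
    support: dict[str, set[str]] = defaultdict(set)
    for m in mappings:
        if m.is_perfect and m.is_specific:
            (gene,) = m.gene_ids
            support[gene].add(m.probe_id)
    rows = []
    whitelisted = set(whitelist)
    for gene in sorted(support):
        probes = support[gene]
        if len(probes) < min_probes:
            continue
        if gene not in gene_meta.index:
            raise KeyError(f"gene {gene!r} missing from the annotation table")
        meta = gene_meta.loc[gene]
        if meta["biotype"] not in whitelisted:
            continue
        rows.append(
            {
                "gene_id": gene,
                "gene_symbol": meta["gene_symbol"],
                "biotype": meta["biotype"],
                "probe_ids": ",".join(sorted(probes)),
                "n_probes": len(probes),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "gene_symbol", "biotype", "probe_ids", "n_probes"]
    )


def aggregate_to_lncrna(
    probe_matrix: pd.DataFrame, table: pd.DataFrame
) -> pd.DataFrame:
    """Collapse probe-level expression to gene level by the mean rule.

    Each retained gene's row is the arithmetic mean, per sample, of its
    supporting probes' rows; sample order is preserved.
    """
    rows = {}
    for rec in table.itertuples(index=False):
        probe_ids = rec.probe_ids.split(",")
        missing = [p for p in probe_ids if p not in probe_matrix.index]
        if missing:
            raise KeyError(
                f"gene {rec.gene_id}: probes missing from matrix: {missing}"
            )
        rows[rec.gene_id] = probe_matrix.loc[probe_ids].mean(axis=0)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene_id"
    if out.empty:
        out = pd.DataFrame(
            np.empty((0, probe_matrix.shape[1])), columns=probe_matrix.columns
        )
        out.index.name = "gene_id"
    return out.reindex(columns=probe_matrix.columns)
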