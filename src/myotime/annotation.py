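"""Structural categorization of transcripts and coding-confidence triage.

A query transcript is compared with a reference transcript set and its
splice-junction catalog at the junction-chain level:

* FSM (full splice match) — junction chain identical to a reference
  transcript on the same chromosome and strand;
* NIC (novel in catalog) — every junction individually known, but the chain
  matches no reference transcript;
* NNC (novel not in catalog) — at least one junction absent from the catalog;
* mono-exonic queries match a mono-exonic reference by exon overlap
  (``mono_exon_match``) or fall into ``other``.

Coding triage consumes externally computed per-isoform mean pLDDT scores
and ORF/protein-match flags: an ORF matching a known protein is
``known_coding`` regardless of structure confidence; otherwise mean pLDDT
strictly above 0.7 (on the 0-1 scale) is ``high_confidence_coding``, else
``low_confidence_coding``; no ORF means ``noncoding``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import JunctionCatalog, TranscriptModel

PLDDT_THRESHOLD = 0.7


@dataclass
class StructuralCall:
    transcript_id: str
    category: str  # FSM | NIC | NNC | mono_exon_match | other
    matched_reference: str | None = None
    novel_junctions: tuple = ()
    flag: str | None = None


def classify_transcript(
    query: TranscriptModel,
    reference: list[TranscriptModel],
    catalog: JunctionCatalog,
) -> StructuralCall:
    """Categorize one transcript against the reference set and catalog."""
    ref_chroms = {r.chrom for r in reference}
    if query.chrom not in ref_chroms:
        return StructuralCall(query.transcript_id, "other", flag="unknown_chromosome")

    if len(query.exons) == 1:
        qs, qe = query.exons[0]
        for r in reference:
            if (
                len(r.exons) == 1
                and r.chrom == query.chrom
                and r.strand == query.strand
                and r.exons[0][0] <= qe
                and qs <= r.exons[0][1]
            ):
                return StructuralCall(
                    query.transcript_id, "mono_exon_match", matched_reference=r.transcript_id
                )
        return StructuralCall(query.transcript_id, "other")

    chain = query.junction_keys()
    for r in reference:
        if (
            len(r.exons) > 1
            and r.chrom == query.chrom
            and r.strand == query.strand
            and r.junction_keys() == chain
        ):
            return StructuralCall(
                query.transcript_id, "FSM", matched_reference=r.transcript_id
            )
    novel = tuple(j for j in chain if j not in catalog)
    if novel:
        return StructuralCall(query.transcript_id, "NNC", novel_junctions=novel)
    return StructuralCall(query.transcript_id, "NIC")


def classify_transcripts(
    queries: list[TranscriptModel],
    reference: list[TranscriptModel],
    catalog: JunctionCatalog | None = None,
) -> pd.DataFrame:
    if catalog is None:
        catalog = JunctionCatalog.from_transcripts(reference)
    calls = [classify_transcript(q, reference, catalog) for q in queries]
    return pd.DataFrame(
        {
            "category": [c.category for c in calls],
            "matched_reference": [c.matched_reference for c in calls],
            "n_novel_junctions": [len(c.novel_junctions) for c in calls],
        },
        index=pd.Index([c.transcript_id for c in calls], name="transcript_id"),
    )


def normalize_plddt(values: pd.Series) -> pd.Series:
    """Map mean pLDDT onto [0, 1]; inputs on the 0-100 scale are divided by 100."""
    v = values.astype(float).copy()
    big = v > 1.0
    v[big] = v[big] / 100.0
    if ((v < 0) | (v > 1)).any():
        bad = v.index[(v < 0) | (v > 1)][0]
        raise ValueError(f"pLDDT outside [0, 1] after normalization: {bad!r}")
    return v


def coding_triage(
    orf_table: pd.DataFrame,
    plddt: pd.Series,
    threshold: float = PLDDT_THRESHOLD,
) -> pd.DataFrame:
    """Triage transcripts into known/high/low-confidence coding or noncoding.

    ``orf_table`` needs boolean columns ``has_orf`` and ``orf_matches_known``.
    A missing pLDDT for an ORF-bearing novel transcript yields
    ``low_confidence_coding`` with a ``missing_plddt`` flag.
    """
    plddt = normalize_plddt(plddt)
    rows = []
    for tid, row in orf_table.iterrows():
        flag = None
        if not row["has_orf"]:
            triage = "noncoding"
        elif row["orf_matches_known"]:
            triage = "known_coding"
        elif tid not in plddt.index or pd.isna(plddt.get(tid)):
            triage, flag = "low_confidence_coding", "missing_plddt"
        elif plddt[tid] > threshold:
            triage = "high_confidence_coding"
        else:
            triage = "low_confidence_coding"
        rows.append((tid, triage, flag, plddt.get(tid, np.nan)))
    return pd.DataFrame(
        rows, columns=["transcript_id", "triage", "flag", "mean_plddt"]
    ).set_index("transcript_id")


def category_summary(
    calls: pd.DataFrame,
    triage: pd.DataFrame,
    cluster_assignments: pd.Series,
) -> pd.DataFrame:
    """Counts per (cluster, structural category x coding triage) cell."""
    common = calls.index.intersection(triage.index).intersection(
        cluster_assignments.index
    )
    combo = calls.loc[common, "category"] + "/" + triage.loc[common, "triage"]
    table = pd.crosstab(cluster_assignments.loc[common], combo)
    table.index.name = "cluster"
    table.columns.name = "category_triage"
    return table
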