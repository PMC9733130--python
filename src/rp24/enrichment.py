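"""Promoter extraction and motif-enrichment statistics for transcript groups.

A transcript's promoter is the up-to-6000-nt region upstream of its annotated
transcription start site plus its first intron (transcript order), joined by
a 20-N linker so no motif can span the junction.  Motif occurrences come from
an external FIMO scan; enrichment of motif-bearing promoters in a transcript
cluster against the global promoter universe uses the upper-tail
hypergeometric test with Benjamini-Hochberg correction across motifs within
each cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

from .inference import bh_qvalues

logger = logging.getLogger(__name__)

__all__ = [
    "PromoterRecord",
    "MotifOccurrenceTable",
    "EnrichmentResult",
    "extract_promoters",
    "load_fimo",
    "motif_enrichment",
    "motif_effect_tests",
    "hypergeom_tail",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PromoterRecord:
    """Sense-strand promoter sequence with its genomic provenance."""

    transcript_id: str
    sequence: str
    chrom: str
    strand: str
    upstream_interval: tuple[int, int]  # 1-based inclusive
    intron_interval: tuple[int, int] | None  # None if single-exon


@dataclass(frozen=True)
class MotifOccurrenceTable:
    """Presence/absence of each motif per promoter, with the scanned universe."""

    universe: frozenset
    hits: dict  # motif_id -> frozenset of promoter/transcript ids

    def __post_init__(self) -> None:
        for motif, promoters in self.hits.items():
            if not promoters <= self.universe:
                raise ValueError(f"hits for {motif} outside the universe")


@dataclass(frozen=True)
class EnrichmentResult:
    cluster_id: str
    motif_id: str
    k: int  # cluster promoters with the motif
    n: int  # cluster size
    K: int  # universe promoters with the motif
    M: int  # universe size
    p: float
    q: float = float("nan")


def extract_promoters(
    annotation_path: str,
    genome_path: str,
    upstream: int = 6000,
    linker: int = 20,
) -> list[PromoterRecord]:
    """Strand-aware promoter extraction from GFF3 annotation and FASTA genome.

    The upstream window is clipped at the chromosome boundary; the first
    intron is the gap between exon 1 and exon 2 in transcript order.
    Single-exon transcripts contribute the upstream segment only (no linker).
    Transcripts on contigs missing from the genome are skipped with a warning.
    """
    import gffutils
    from pyfaidx import Fasta

    db = gffutils.create_db(
        annotation_path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genome = Fasta(genome_path, as_raw=True, sequence_always_upper=True)

    records: list[PromoterRecord] = []
    feature_types = {"mRNA", "transcript"}
    for tx in db.all_features():
        if tx.featuretype not in feature_types:
            continue
        tid = tx.attributes.get("ID", [tx.id])[0]
        if tx.seqid not in genome:
            logger.warning("transcript %s: contig %s missing from genome; skipped", tid, tx.seqid)
            continue
        chrom_len = len(genome[tx.seqid])
        exons = list(db.children(tx, featuretype="exon"))
        strand = tx.strand
        if strand == "+":
            tss = tx.start
            up_start = max(1, tss - upstream)
            up_end = tss - 1
            exons.sort(key=lambda e: e.start)
        elif strand == "-":
            tss = tx.end
            up_start = tss + 1
            up_end = min(chrom_len, tss + upstream)
            exons.sort(key=lambda e: e.start, reverse=True)
        else:
            logger.warning("transcript %s: strand %r; skipped", tid, strand)
            continue

        if up_end >= up_start:
            up_seq = genome[tx.seqid][up_start - 1 : up_end]  # 1-based inclusive
        else:
            up_seq = ""
        intron_interval = None
        intron_seq = ""
        if len(exons) >= 2:
            e1, e2 = exons[0], exons[1]
            if strand == "+":
                i_start, i_end = e1.end + 1, e2.start - 1
            else:
                i_start, i_end = e2.end + 1, e1.start - 1
            if i_end >= i_start:
                intron_interval = (i_start, i_end)
                intron_seq = genome[tx.seqid][i_start - 1 : i_end]
        if strand == "-":
            up_seq = _revcomp(up_seq)
            intron_seq = _revcomp(intron_seq)
        if intron_seq:
            sequence = up_seq + "N" * linker + intron_seq
        else:
            sequence = up_seq
        records.append(
            PromoterRecord(
                transcript_id=tid,
                sequence=sequence,
                chrom=tx.seqid,
                strand=strand,
                upstream_interval=(up_start, up_end),
                intron_interval=intron_interval,
            )
        )
    return records


_FIMO_REQUIRED = ["motif_id", "sequence_name", "start", "stop", "strand", "score", "p-value"]


def load_fimo(
    scan_path: str,
    p_thresh: float = 5e-5,
    universe=None,
) -> MotifOccurrenceTable:
    """Collapse a FIMO occurrence table to per-promoter motif presence.

    Occurrences with p-value > ``p_thresh`` are discarded.  ``universe``
    (all scanned promoter ids) defaults to the sequence names present in the
    scan, but should be supplied as the full promoter list: sequences with no
    occurrence at all do not appear in FIMO output.
    """
    df = pd.read_csv(scan_path, sep="\t", comment=None)
    df.columns = [c.lstrip("# ") for c in df.columns]
    missing = [c for c in _FIMO_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"FIMO table missing required columns: {missing}")
    kept = df[df["p-value"] <= p_thresh]
    hits = {
        motif: frozenset(group["sequence_name"].astype(str))
        for motif, group in kept.groupby("motif_id")
    }
    if universe is None:
        universe = frozenset(df["sequence_name"].astype(str))
    else:
        universe = frozenset(str(u) for u in universe)
    return MotifOccurrenceTable(universe=universe, hits=hits)


def hypergeom_tail(k: int, M: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k) with X ~ Hypergeom(M, K, n)."""
    if k <= 0:
        return 1.0
    return float(_st.hypergeom.sf(k - 1, M, K, n))


def motif_enrichment(
    cluster,
    table: MotifOccurrenceTable,
    cluster_id: str = "cluster",
    min_cluster_size: int = 10,
) -> list[EnrichmentResult]:
    """Hypergeometric motif enrichment of a transcript cluster vs the universe.

    BH correction is applied across motifs within the cluster.  Clusters not
    contained in the universe are rejected; clusters below
    ``min_cluster_size`` raise (set it to 0 to disable the rule).
    """
    cluster = frozenset(str(c) for c in cluster)
    if not cluster <= table.universe:
        raise ValueError(
            f"cluster contains ids outside the universe: {sorted(cluster - table.universe)[:5]}"
        )
    if len(cluster) < min_cluster_size:
        raise ValueError(
            f"cluster size {len(cluster)} below the inclusion minimum {min_cluster_size}"
        )
    M = len(table.universe)
    n = len(cluster)
    results = []
    for motif_id in sorted(table.hits):
        promoters = table.hits[motif_id]
        K = len(promoters)
        k = len(promoters & cluster)
        p = hypergeom_tail(k, M, K, n)
        results.append(
            EnrichmentResult(cluster_id=cluster_id, motif_id=motif_id, k=k, n=n, K=K, M=M, p=p)
        )
    if results:
        qs = bh_qvalues([r.p for r in results])
        results = [
            EnrichmentResult(
                cluster_id=r.cluster_id, motif_id=r.motif_id,
                k=r.k, n=r.n, K=r.K, M=r.M, p=r.p, q=float(q),
            )
            for r, q in zip(results, qs)
        ]
    return results


def motif_effect_tests(
    cluster,
    table: MotifOccurrenceTable,
    stats_by_transcript: dict,
    motifs=None,
) -> pd.DataFrame:
    """Welch comparisons of RP24 and expression, motif-present vs motif-absent.

    Within the cluster, transcripts are split by presence of each motif and
    compared with Welch's unequal-variance t-test on the RP24 score and on the
    median expression level.  Subgroups smaller than 2 are marked untestable.
    """
    cluster = [str(c) for c in cluster]
    if motifs is None:
        motifs = sorted(table.hits)
    rows = []
    for motif in motifs:
        present_ids = [t for t in cluster if t in table.hits.get(motif, frozenset())]
        absent_ids = [t for t in cluster if t not in table.hits.get(motif, frozenset())]
        row = {"motif_id": motif, "n_present": len(present_ids), "n_absent": len(absent_ids)}
        for quantity, attr in (("rp24", "rp24"), ("expression", "median_expr")):
            a = np.array([getattr(stats_by_transcript[t], attr) for t in present_ids], float)
            b = np.array([getattr(stats_by_transcript[t], attr) for t in absent_ids], float)
            a = a[np.isfinite(a)]
            b = b[np.isfinite(b)]
            if len(a) < 2 or len(b) < 2:
                row[f"t_{quantity}"] = np.nan
                row[f"p_{quantity}"] = np.nan
                row[f"testable_{quantity}"] = False
            else:
                if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
                    t, p = 0.0, 1.0
                else:
                    t, p = _st.ttest_ind(a, b, equal_var=False)
                row[f"t_{quantity}"] = float(t)
                row[f"p_{quantity}"] = float(p)
                row[f"testable_{quantity}"] = True
        rows.append(row)
    return pd.DataFrame(rows)
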