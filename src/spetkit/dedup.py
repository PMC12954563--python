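"""UMI-based removal of PCR/optical duplicates from aligned capture reads.

SPET library preparation tags every original DNA fragment with a 6 bp
unique molecular identifier (UMI) before amplification, so reads that
share an alignment start, strand and UMI are copies of one fragment.
One representative per group is retained (highest mean base quality,
ties broken by read id), which makes downstream depth a count of
original molecules rather than PCR copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class AlignedReadRecord:
    """One aligned read with its UMI.

    ``start`` is the 0-based leftmost aligned base of read 1; ``length``
    the aligned length (used by probe QC pileups, not by dedup).
    """

    read_id: str
    umi: str
    seq_id: str
    start: int
    strand: str
    mean_qual: float = 30.0
    length: int = 150

    def __post_init__(self) -> None:
        if set(self.umi) - _DNA:
            raise ValueError(f"{self.read_id}: UMI {self.umi!r} not over ACGT")
        if self.start < 0:
            raise ValueError(f"{self.read_id}: negative start")


@dataclass
class DedupReport:
    n_input: int
    n_retained: int
    n_duplicates: int
    n_groups: int
    duplicate_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_input": self.n_input,
                    "n_retained": self.n_retained,
                    "n_duplicates": self.n_duplicates,
                    "n_groups": self.n_groups,
                }
            ]
        )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _cluster_umis(umis: list[str], max_mismatch: int) -> dict[str, str]:
    """Map each UMI to a cluster representative.

    Connected components under Hamming distance <= max_mismatch, built
    by union over the (small) set of distinct UMIs sharing one position
    key.  With max_mismatch=0 every UMI is its own cluster.
    """
    distinct = sorted(set(umis))
    if max_mismatch == 0 or len(distinct) == 1:
        return {u: u for u in distinct}
    parent = {u: u for u in distinct}

    def find(u: str) -> str:
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for i, a in enumerate(distinct):
        for b in distinct[i + 1 :]:
            if _hamming(a, b) <= max_mismatch:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    return {u: find(u) for u in distinct}


def dedup(
    records: Sequence[AlignedReadRecord],
    umi_mismatch: int = 0,
) -> tuple[list[AlignedReadRecord], DedupReport]:
    """Collapse duplicate reads sharing (seq_id, start, strand, UMI).

    With ``umi_mismatch`` > 0, UMIs within that Hamming distance at one
    position key are merged (sequencing errors in the UMI itself).  The
    retained representative of each group is the read with the highest
    mean base quality; ties go to the lexicographically smallest
    read_id.  Deterministic and idempotent.
    """
    if not records:
        return [], DedupReport(0, 0, 0, 0)
    umi_len = len(records[0].umi)
    if any(len(r.umi) != umi_len for r in records):
        raise ValueError("inconsistent UMI length across records")
    by_pos: dict[tuple[str, int, str], list[AlignedReadRecord]] = {}
    for r in records:
        by_pos.setdefault((r.seq_id, r.start, r.strand), []).append(r)
    retained: list[AlignedReadRecord] = []
    dup_ids: list[str] = []
    n_groups = 0
    for key in sorted(by_pos):
        recs = by_pos[key]
        cluster_of = _cluster_umis([r.umi for r in recs], umi_mismatch)
        groups: dict[str, list[AlignedReadRecord]] = {}
        for r in recs:
            groups.setdefault(cluster_of[r.umi], []).append(r)
        for cl in sorted(groups):
            group = groups[cl]
            n_groups += 1
            best = min(group, key=lambda r: (-r.mean_qual, r.read_id))
            retained.append(best)
            dup_ids.extend(r.read_id for r in group if r is not best)
    retained.sort(key=lambda r: (r.seq_id, r.start, r.strand, r.read_id))
    report = DedupReport(
        n_input=len(records),
        n_retained=len(retained),
        n_duplicates=len(dup_ids),
        n_groups=n_groups,
        duplicate_ids=sorted(dup_ids),
    )
    return retained, report


# ---------------------------------------------------------------------------
# SAM interchange
# ---------------------------------------------------------------------------


def umi_from_name(read_name: str) -> str:
    """UMI parsed from the read-name suffix after the last ':'."""
    return read_name.rsplit(":", 1)[-1]


def records_from_sam(path, umi_from: str = "name", umi_tag: str = "RX") -> list[AlignedReadRecord]:
    """Load aligned reads from SAM/BAM with UMIs in the name or a tag."""
    import pysam

    records = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_paired and not aln.is_read1:
                continue
            if umi_from == "name":
                umi = umi_from_name(aln.query_name)
            else:
                umi = str(aln.get_tag(umi_tag))
            quals = aln.query_qualities
            mq = float(sum(quals)) / len(quals) if quals else 30.0
            records.append(
                AlignedReadRecord(
                    read_id=aln.query_name,
                    umi=umi,
                    seq_id=aln.reference_name,
                    start=aln.reference_start,
                    strand="-" if aln.is_reverse else "+",
                    mean_qual=mq,
                    length=aln.query_length or 150,
                )
            )
    return records


def write_records_sam(records: Iterable[AlignedReadRecord], ref_lengths: dict[str, int], path) -> None:
    """Write records as minimal single-end SAM text."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for sid, ln in ref_lengths.items():
            fh.write(f"@SQ\tSN:{sid}\tLN:{ln}\n")
        for r in records:
            flag = 16 if r.strand == "-" else 0
            fh.write(
                f"{r.read_id}\t{flag}\t{r.seq_id}\t{r.start + 1}\t60\t"
                f"{r.length}M\t*\t0\t0\t*\t*\tRX:Z:{r.umi}\n"
            )
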