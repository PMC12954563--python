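"""Per-probe depth QC, working-probe classification, captured bases.

A probe is *working* when its target position reaches a deduplicated
depth of at least 6x in at least 50% of the analysed samples (both
bounds inclusive).  Captured genome size counts the positions that meet
the same criterion across probe-flanking windows.  Transferability
summaries cross-tabulate working probes by the species the probe was
originally designed for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from spetkit.dedup import AlignedReadRecord
from spetkit.panel import PanelManifest


def depth_at_targets(
    records_by_sample: Mapping[str, Sequence[AlignedReadRecord]],
    panel: PanelManifest,
) -> pd.DataFrame:
    """Probes x samples depth at the target position.

    Depth is the number of (deduplicated) reads whose aligned span
    covers the probe's target position.  Samples with zero reads yield
    a zero column with a warning.
    """
    samples = list(records_by_sample)
    mat = pd.DataFrame(
        0, index=[p.probe_id for p in panel.probes], columns=samples, dtype=int
    )
    targets_by_seq: dict[str, list[tuple[int, str]]] = {}
    for p in panel.probes:
        targets_by_seq.setdefault(p.seq_id, []).append((p.target_pos, p.probe_id))
    for sample, records in records_by_sample.items():
        if not records:
            warnings.warn(f"sample {sample!r} has zero reads")
            continue
        for r in records:
            for tpos, pid in targets_by_seq.get(r.seq_id, ()):
                if r.start <= tpos < r.start + r.length:
                    mat.loc[pid, sample] += 1
    return mat


@dataclass
class ProbeStatus:
    probe_id: str
    working: bool
    frac_samples_ge_min: float
    mean_depth_working_samples: float


def working_probes(
    depth: pd.DataFrame,
    panel: PanelManifest,
    min_depth: int = 6,
    min_frac: float = 0.5,
) -> tuple[list[ProbeStatus], pd.DataFrame]:
    """Classify probes as working and summarise by type and origin.

    working ⟺ (#samples with depth >= min_depth) / n_samples >= min_frac
    (inclusive on both thresholds).
    """
    if depth.empty:
        raise ValueError("empty depth matrix")
    meta = {p.probe_id: p for p in panel.probes}
    statuses: list[ProbeStatus] = []
    n_samples = depth.shape[1]
    for pid, row in depth.iterrows():
        ge = row >= min_depth
        frac = float(ge.sum()) / n_samples
        mean_working = float(row[ge].mean()) if ge.any() else float("nan")
        statuses.append(
            ProbeStatus(
                probe_id=pid,
                working=frac >= min_frac,
                frac_samples_ge_min=frac,
                mean_depth_working_samples=mean_working,
            )
        )
    rows = []
    for st in statuses:
        p = meta.get(st.probe_id)
        rows.append(
            {
                "probe_id": st.probe_id,
                "working": st.working,
                "site_type": p.site_type.value if p else "unknown",
                "origin_species": p.origin_species if p else "unknown",
            }
        )
    df = pd.DataFrame(rows)
    summary = (
        df.groupby(["site_type", "origin_species"])["working"]
        .agg(n_probes="size", n_working="sum")
        .reset_index()
    )
    return statuses, summary


def per_position_depth(
    records_by_sample: Mapping[str, Sequence[AlignedReadRecord]],
    intervals: Sequence[tuple[str, int, int]],
) -> dict[tuple[str, int], np.ndarray]:
    """Per-position, per-sample depth over the given genomic intervals.

    Returns a dict mapping (seq_id, position) to a depth vector in the
    order of ``records_by_sample``'s keys.
    """
    samples = list(records_by_sample)
    depth: dict[tuple[str, int], np.ndarray] = {}
    for sid, start, end in intervals:
        for pos in range(start, end):
            depth.setdefault((sid, pos), np.zeros(len(samples), dtype=int))
    for si, (sample, records) in enumerate(records_by_sample.items()):
        for r in records:
            for pos in range(r.start, r.start + r.length):
                v = depth.get((r.seq_id, pos))
                if v is not None:
                    v[si] += 1
    return depth


def captured_bases(
    depth: Mapping[tuple[str, int], np.ndarray],
    min_depth: int = 6,
    min_frac: float = 0.5,
) -> tuple[int, pd.DataFrame]:
    """Genome positions covered >= min_depth in >= min_frac of samples.

    Returns the qualifying base count and a merged BED-like frame of
    captured intervals (chrom, start, end; 0-based half-open).
    """
    qualifying: dict[str, list[int]] = {}
    for (sid, pos), vec in depth.items():
        if len(vec) and (vec >= min_depth).sum() / len(vec) >= min_frac:
            qualifying.setdefault(sid, []).append(pos)
    total = sum(len(v) for v in qualifying.values())
    rows = []
    for sid in sorted(qualifying):
        positions = sorted(qualifying[sid])
        start = prev = positions[0]
        for p in positions[1:]:
            if p == prev + 1:
                prev = p
                continue
            rows.append({"chrom": sid, "start": start, "end": prev + 1})
            start = prev = p
        rows.append({"chrom": sid, "start": start, "end": prev + 1})
    return total, pd.DataFrame(rows, columns=["chrom", "start", "end"])


def transferability_summary(
    status_by_run: Mapping[str, Sequence[ProbeStatus]],
    panel: PanelManifest,
) -> pd.DataFrame:
    """Cross-tab of working probes: rows = genotyped run, cols = origin.

    All runs must share the panel; the row sums equal each run's total
    working-probe count.
    """
    origin = {p.probe_id: p.origin_species for p in panel.probes}
    panel_ids = set(origin)
    rows = {}
    for run, statuses in status_by_run.items():
        ids = {st.probe_id for st in statuses}
        if not ids <= panel_ids:
            raise ValueError(f"run {run!r} contains probes not in the panel")
        counts: dict[str, int] = {}
        for st in statuses:
            if st.working:
                sp = origin[st.probe_id]
                counts[sp] = counts.get(sp, 0) + 1
        rows[run] = counts
    return pd.DataFrame(rows).T.fillna(0).astype(int)
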