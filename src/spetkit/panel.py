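"""Target-site selection and probe manifest assembly.

A SPET panel mixes two site classes: *random* sites drawn from eligible
low-repetitiveness regions (ascertainment-bias-free, suitable for
diversity estimation) and *known* sites imported from earlier resources
(arrays, previous panels, candidate genes).  At least half of the panel
must be random sites, so that diversity statistics computed downstream
are not dominated by markers pre-selected for intermediate frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from spetkit.kmer import EligibleRegion, ReferenceSequence, revcomp


class SiteType(str, Enum):
    random = "random"
    known = "known"


@dataclass(frozen=True)
class TargetSite:
    seq_id: str
    pos: int  # 0-based
    site_type: SiteType
    origin_species: str = "."
    ref_allele: str | None = None


@dataclass(frozen=True)
class Probe:
    probe_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    sequence: str
    target_pos: int
    site_type: SiteType
    origin_species: str


@dataclass
class PanelManifest:
    panel_name: str
    probes: list[Probe] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.probe_id for p in self.probes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate probe_ids in panel")

    @property
    def n_random(self) -> int:
        return sum(p.site_type is SiteType.random for p in self.probes)

    @property
    def n_total(self) -> int:
        return len(self.probes)

    def summary(self) -> pd.DataFrame:
        rows = [
            {"site_type": p.site_type.value, "origin_species": p.origin_species}
            for p in self.probes
        ]
        df = pd.DataFrame(rows)
        return df.groupby(["site_type", "origin_species"]).size().rename("n").reset_index()


def select_random_sites(
    regions: Sequence[EligibleRegion],
    n: int,
    seed: int,
    min_spacing: int = 1000,
) -> list[TargetSite]:
    """Draw ``n`` random target sites from eligible regions.

    Sites are drawn uniformly without replacement over all region
    positions, subject to a pairwise spacing of at least ``min_spacing``
    bp within each reference sequence (spacing avoids redundant capture
    of one locus by several probes).  Deterministic given ``seed``.

    Raises a capacity error naming the shortfall when the spacing
    constraint cannot accommodate ``n`` sites.
    """
    if not regions:
        raise ValueError("no eligible regions supplied")
    if n < 1:
        raise ValueError("n must be >= 1")
    capacity = sum((len(r) - 1) // min_spacing + 1 for r in regions)
    if n > capacity:
        raise ValueError(
            f"cannot place {n} sites with min_spacing={min_spacing}: "
            f"capacity is {capacity} (short by {n - capacity})"
        )
    rng = np.random.default_rng(seed)
    candidates = [(r.seq_id, p) for r in regions for p in range(r.start, r.end)]
    order = rng.permutation(len(candidates))
    chosen: dict[str, list[int]] = {}
    n_chosen = 0

    def fits(sid: str, pos: int) -> bool:
        return all(abs(pos - q) >= min_spacing for q in chosen.get(sid, ()))

    for idx in order:
        if n_chosen == n:
            break
        sid, pos = candidates[idx]
        if fits(sid, pos):
            chosen.setdefault(sid, []).append(pos)
            n_chosen += 1
    if n_chosen < n:
        # deterministic left-to-right fill over remaining positions
        for sid, pos in candidates:
            if n_chosen == n:
                break
            if fits(sid, pos):
                chosen.setdefault(sid, []).append(pos)
                n_chosen += 1
    if n_chosen < n:
        raise ValueError(
            f"cannot place {n} sites with min_spacing={min_spacing}: "
            f"placed only {n_chosen} (short by {n - n_chosen})"
        )
    sites = [
        TargetSite(sid, pos, SiteType.random)
        for sid, poss in chosen.items()
        for pos in poss
    ]
    sites.sort(key=lambda s: (s.seq_id, s.pos))
    return sites


def load_known_targets(path, origin_species: str = ".") -> list[TargetSite]:
    """Read known target SNPs from a VCF or BED file.

    BED intervals longer than 1 bp contribute a site at the interval
    start (with a warning); duplicated positions are collapsed.
    """
    path = Path(path)
    if path.suffix.lower() in {".bed", ".txt", ".tsv"}:
        sites = _load_targets_bed(path, origin_species)
    else:
        sites = _load_targets_vcf(path, origin_species)
    seen: set[tuple[str, int]] = set()
    out: list[TargetSite] = []
    for s in sites:
        key = (s.seq_id, s.pos)
        if key in seen:
            warnings.warn(f"duplicate known target at {s.seq_id}:{s.pos + 1}, collapsed")
            continue
        seen.add(key)
        out.append(s)
    out.sort(key=lambda s: (s.seq_id, s.pos))
    return out


def _load_targets_bed(path: Path, origin_species: str) -> list[TargetSite]:
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED record") from exc
            if end - start > 1:
                warnings.warn(
                    f"{path}:{lineno}: interval of length {end - start}, "
                    "using interval start as the target site"
                )
            sites.append(TargetSite(chrom, start, SiteType.known, origin_species))
    return sites


def _load_targets_vcf(path: Path, origin_species: str) -> list[TargetSite]:
    from cyvcf2 import VCF

    sites = []
    for v in VCF(str(path)):
        sites.append(
            TargetSite(v.CHROM, v.POS - 1, SiteType.known, origin_species, v.REF)
        )
    return sites


def assemble_panel(
    random_sites: Sequence[TargetSite],
    known_sites: Sequence[TargetSite],
    total: int,
    min_random_frac: float = 0.5,
    seed: int = 0,
    panel_name: str = "panel",
) -> list[TargetSite]:
    """Combine random and known sites into a panel of ``total`` sites.

    Known sites are capped at ``(1 - min_random_frac) * total`` (uniform
    seeded subsampling when they exceed the cap); random sites fill the
    remainder.  A position present in both lists is kept as known.
    Returns the ordered target list; :func:`emit_probe_manifest` turns
    it into probes.
    """
    known = list(known_sites)
    known_pos = {(s.seq_id, s.pos) for s in known}
    random_ = [s for s in random_sites if (s.seq_id, s.pos) not in known_pos]
    if len(random_) + len(known) < total:
        raise ValueError(
            f"only {len(random_) + len(known)} candidate sites for total={total}"
        )
    rng = np.random.default_rng(seed)
    max_known = int((1.0 - min_random_frac) * total)
    if len(known) > max_known:
        keep = rng.choice(len(known), size=max_known, replace=False)
        known = [known[i] for i in sorted(keep)]
    n_random_needed = total - len(known)
    if n_random_needed > len(random_):
        raise ValueError(
            f"need {n_random_needed} random sites to satisfy "
            f"min_random_frac={min_random_frac} but only {len(random_)} available"
        )
    if n_random_needed < len(random_):
        keep = rng.choice(len(random_), size=n_random_needed, replace=False)
        random_ = [random_[i] for i in sorted(keep)]
    sites = sorted(random_ + known, key=lambda s: (s.seq_id, s.pos))
    n_random = sum(s.site_type is SiteType.random for s in sites)
    assert n_random / total >= min_random_frac - 1e-12
    return sites


def emit_probe_manifest(
    sites: Sequence[TargetSite],
    refs: Sequence[ReferenceSequence] | Mapping[str, str],
    probe_len: int = 40,
    strand_rule: str = "plus",
    panel_name: str = "panel",
) -> PanelManifest:
    """Construct probes for target sites.

    The probe is the ``probe_len`` reference bases immediately 5' of the
    target on the chosen strand, so that single-primer extension from
    the probe's 3' end sequences across the target position.  On '+',
    the probe covers ``[pos - probe_len, pos)``; on '-', it covers
    ``[pos + 1, pos + 1 + probe_len)`` and its sequence is the reverse
    complement of that slice.

    ``strand_rule``: ``plus`` always uses '+'; ``auto`` falls back to
    '-' when the 5' flank is too short.  Targets with no usable flank
    are skipped with a warning.
    """
    if strand_rule not in {"plus", "auto"}:
        raise ValueError(f"unknown strand_rule {strand_rule!r}")
    if isinstance(refs, Mapping):
        seqs = {k: v.upper() for k, v in refs.items()}
    else:
        seqs = {r.seq_id: r.residues.upper() for r in refs}
    probes: list[Probe] = []
    for i, site in enumerate(sites):
        seq = seqs.get(site.seq_id)
        if seq is None:
            raise KeyError(f"target on unknown sequence {site.seq_id!r}")
        strand = "+"
        if site.pos - probe_len < 0:
            if strand_rule == "auto" and site.pos + 1 + probe_len <= len(seq):
                strand = "-"
            else:
                warnings.warn(
                    f"target {site.seq_id}:{site.pos + 1} too close to sequence "
                    "end for probe design; skipped"
                )
                continue
        if strand == "+":
            start, end = site.pos - probe_len, site.pos
            sequence = seq[start:end]
        else:
            start, end = site.pos + 1, site.pos + 1 + probe_len
            sequence = revcomp(seq[start:end])
        if "N" in sequence:
            warnings.warn(
                f"probe for {site.seq_id}:{site.pos + 1} contains N; skipped"
            )
            continue
        probes.append(
            Probe(
                probe_id=f"{panel_name}_{i:06d}",
                seq_id=site.seq_id,
                start=start,
                end=end,
                strand=strand,
                sequence=sequence,
                target_pos=site.pos,
                site_type=site.site_type,
                origin_species=site.origin_species,
            )
        )
    return PanelManifest(panel_name=panel_name, probes=probes)


MANIFEST_COLUMNS = [
    "probe_id",
    "seq_id",
    "start",
    "end",
    "strand",
    "sequence",
    "target_pos_1based",
    "site_type",
    "origin_species",
]


def write_manifest(panel: PanelManifest, out_dir) -> dict[str, Path]:
    """Write TSV manifest + probe FASTA + target BED into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "probe_id": p.probe_id,
            "seq_id": p.seq_id,
            "start": p.start,
            "end": p.end,
            "strand": p.strand,
            "sequence": p.sequence,
            "target_pos_1based": p.target_pos + 1,
            "site_type": p.site_type.value,
            "origin_species": p.origin_species,
        }
        for p in panel.probes
    ]
    tsv = out_dir / f"{panel.panel_name}.manifest.tsv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(tsv, sep="\t", index=False)
    fasta = out_dir / f"{panel.panel_name}.probes.fasta"
    with open(fasta, "w") as fh:
        for p in panel.probes:
            fh.write(f">{p.probe_id}\n{p.sequence}\n")
    bed = out_dir / f"{panel.panel_name}.targets.bed"
    with open(bed, "w") as fh:
        for p in panel.probes:
            fh.write(
                f"{p.seq_id}\t{p.target_pos}\t{p.target_pos + 1}\t"
                f"{p.probe_id}\t0\t{p.strand}\n"
            )
    return {"manifest": tsv, "fasta": fasta, "bed": bed}


def read_manifest(path, panel_name: str | None = None) -> PanelManifest:
    """Re-read a TSV manifest written by :func:`write_manifest`."""
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str})
    probes = [
        Probe(
            probe_id=row.probe_id,
            seq_id=str(row.seq_id),
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            sequence=row.sequence,
            target_pos=int(row.target_pos_1based) - 1,
            site_type=SiteType(row.site_type),
            origin_species=str(row.origin_species),
        )
        for row in df.itertuples()
    ]
    if panel_name is None:
        panel_name = Path(path).name.split(".manifest")[0]
    return PanelManifest(panel_name=panel_name, probes=probes)
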