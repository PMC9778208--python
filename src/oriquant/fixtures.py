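"""Synthetic S. cerevisiae-like annotation fixture.

Builds a deterministic, fully synthetic origin annotation shaped like the
standard budding-yeast reference sets: 16 chromosomes at the sacCer3
lengths, 410 confirmed origins (OriDB-style counts), 95 Fkh-activated, 35
Fkh1-sensitive (a subset of the Fkh-activated list), two rDNA-locus origins
on chromosome XII, and one centromere per chromosome. Origin and centromere
*positions* are synthetic (evenly spaced origins; centromeres at 45% of
chromosome length) — only the counts and layout mirror the real genome, so
the fixture exercises set construction, not real coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeBuild, GenomicInterval
from .origins import Centromere, Origin, OriginSet

__all__ = ["SACCER_CHROM_SIZES", "yeastlike_fixture"]

#: sacCer3 chromosome lengths (bp), chrI..chrXVI.
SACCER_CHROM_SIZES: dict[str, int] = {
    "chrI": 230218, "chrII": 813184, "chrIII": 316620, "chrIV": 1531933,
    "chrV": 576874, "chrVI": 270161, "chrVII": 1090940, "chrVIII": 562643,
    "chrIX": 439888, "chrX": 745751, "chrXI": 666816, "chrXII": 1078177,
    "chrXIII": 924431, "chrXIV": 784333, "chrXV": 1091291, "chrXVI": 948066,
}

N_CONFIRMED = 410
N_FKH_ACTIVATED = 95
N_FKH1_SENSITIVE = 35
N_RDNA = 2


def _apportion(total: int, lengths: list[int], minimum: int) -> list[int]:
    """Largest-remainder apportionment of ``total`` origins by length."""
    weights = np.array(lengths, dtype=float)
    raw = total * weights / weights.sum()
    counts = np.maximum(np.floor(raw).astype(int), minimum)
    while counts.sum() < total:
        counts[np.argmax(raw - counts)] += 1
    while counts.sum() > total:
        over = np.where(counts > minimum)[0]
        counts[over[np.argmin((raw - counts)[over])]] -= 1
    return counts.tolist()


def yeastlike_fixture() -> tuple[GenomeBuild, OriginSet, list[Centromere]]:
    """Deterministic synthetic fixture with the standard group counts.

    Returns (genome, origin set, centromeres). Group sizes: 410 confirmed
    (including the 2 rDNA-flagged origins), 95 Fkh-activated, 35
    Fkh1-sensitive; classifying against the 16 centromeres yields 32
    CEN-proximal origins (one per side of each centromere).
    """
    genome = GenomeBuild.from_dict(SACCER_CHROM_SIZES)
    lengths = list(genome.chrom_lengths)
    counts = _apportion(N_CONFIRMED, lengths, minimum=4)
    cens = [
        Centromere(chrom, int(0.45 * length), f"CEN{i + 1}")
        for i, (chrom, length) in enumerate(zip(genome.chrom_names, lengths))
    ]
    origins: list[Origin] = []
    for ci, (chrom, length, n) in enumerate(
        zip(genome.chrom_names, lengths, counts)
    ):
        spacing = length // (n + 1)
        for oi in range(n):
            mid = spacing * (oi + 1)
            start = max(0, mid - 150)
            origins.append(
                Origin(
                    interval=GenomicInterval(
                        chrom, start, min(length, mid + 150),
                        name=f"ARS{ci + 1:02d}{oi + 1:02d}",
                    ),
                    name=f"ARS{ci + 1:02d}{oi + 1:02d}",
                )
            )
    # rDNA: the two origins closest to the rDNA locus (~460 kb on chrXII)
    rdna_target = 460_000
    chr12 = [o for o in origins if o.chrom == "chrXII"]
    rdna_names = {
        o.name
        for o in sorted(chr12, key=lambda o: abs(o.midpoint - rdna_target))[:N_RDNA]
    }
    # Fkh-activated: every 4th confirmed origin in global order, skipping
    # rDNA, until 95 are marked; Fkh1-sensitive: every other one of those.
    fkh_names: list[str] = []
    for o in origins[::4]:
        if o.name not in rdna_names and len(fkh_names) < N_FKH_ACTIVATED:
            fkh_names.append(o.name)
    for o in origins:
        if len(fkh_names) >= N_FKH_ACTIVATED:
            break
        if o.name not in rdna_names and o.name not in fkh_names:
            fkh_names.append(o.name)
    fkh1_sensitive = set(fkh_names[::2][:N_FKH1_SENSITIVE])
    fkh_set = set(fkh_names)
    annotated = [
        Origin(
            interval=o.interval,
            name=o.name,
            confirmed=True,
            fkh_activated=o.name in fkh_set,
            fkh1_sensitive=o.name in fkh1_sensitive,
            rdna=o.name in rdna_names,
        )
        for o in origins
    ]
    return genome, OriginSet(annotated), cens
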