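"""Genome models and copy-number state maps.

A :class:`GenomeModel` describes the reference the pipeline works on: an
ordered set of chromosomes with lengths, a baseline (germline) copy number
per chromosome -- 2 for autosomes, 1 for X and Y in the male samples this
package targets -- and optional masked intervals that are excluded from the
mappable genome (e.g. the Y pseudo-autosomal regions).

A :class:`CopyNumberStateMap` holds the absolute tumour copy number over a
set of non-overlapping genomic intervals; everywhere else the tumour carries
the baseline copy number.  All coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "Chromosome",
    "CopyNumberEvent",
    "CopyNumberStateMap",
    "GenomeModel",
    "HG19_CHROM_LENGTHS",
]

# hg19 chromosome lengths (bp)
HG19_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 249_250_621,
    "chr2": 243_199_373,
    "chr3": 198_022_430,
    "chr4": 191_154_276,
    "chr5": 180_915_260,
    "chr6": 171_115_067,
    "chr7": 159_138_663,
    "chr8": 146_364_022,
    "chr9": 141_213_431,
    "chr10": 135_534_747,
    "chr11": 135_006_516,
    "chr12": 133_851_895,
    "chr13": 115_169_878,
    "chr14": 107_349_540,
    "chr15": 102_531_392,
    "chr16": 90_354_753,
    "chr17": 81_195_210,
    "chr18": 78_077_248,
    "chr19": 59_128_983,
    "chr20": 63_025_520,
    "chr21": 48_129_895,
    "chr22": 51_304_566,
    "chrX": 155_270_560,
    "chrY": 59_373_566,
}

# hg19 Y pseudo-autosomal regions, masked by default in a male genome.
_Y_PAR = ((10_000, 2_649_520), (59_034_049, 59_363_566))


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    baseline_cn: int  # germline copy number: 2 autosome, 1 for X/Y (male)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be > 0")
        if self.baseline_cn not in (1, 2):
            raise ValueError(
                f"chromosome {self.name}: baseline copy number must be 1 or 2"
            )


@dataclass(frozen=True)
class CopyNumberEvent:
    chrom: str
    start: int
    end: int
    copies: float  # absolute tumour copy number, >= 0

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise ValueError("tumour copy number must be >= 0")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")


class GenomeModel:
    """Chromosome set with baseline copy numbers and masked intervals."""

    def __init__(
        self,
        chromosomes: Sequence[Chromosome],
        masked_intervals: dict[str, Sequence[tuple[int, int]]] | None = None,
    ) -> None:
        if not chromosomes:
            raise ValueError("at least one chromosome required")
        names = [c.name for c in chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        self.chromosomes = list(chromosomes)
        self._by_name = {c.name: c for c in self.chromosomes}
        self.masked_intervals: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivls in (masked_intervals or {}).items():
            if chrom not in self._by_name:
                raise ValueError(f"masked interval on unknown chromosome {chrom}")
            length = self._by_name[chrom].length
            merged = _merge_intervals(ivls)
            for s, e in merged:
                if not 0 <= s < e <= length:
                    raise ValueError(
                        f"masked interval {chrom}:{s}-{e} outside chromosome bounds"
                    )
            self.masked_intervals[chrom] = merged

    # -- basic lookups ---------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._by_name

    def chromosome(self, name: str) -> Chromosome:
        return self._by_name[name]

    def length(self, chrom: str) -> int:
        return self._by_name[chrom].length

    def baseline(self, chrom: str) -> int:
        return self._by_name[chrom].baseline_cn

    def autosomes(self) -> list[str]:
        return [c.name for c in self.chromosomes if c.baseline_cn == 2]

    # -- mappability -----------------------------------------------------
    def unmasked_intervals(self, chrom: str) -> list[tuple[int, int]]:
        """Complement of the masked intervals within the chromosome."""
        length = self.length(chrom)
        out: list[tuple[int, int]] = []
        pos = 0
        for s, e in self.masked_intervals.get(chrom, []):
            if s > pos:
                out.append((pos, s))
            pos = max(pos, e)
        if pos < length:
            out.append((pos, length))
        return out

    def mappable_length(self, chrom: str) -> int:
        return sum(e - s for s, e in self.unmasked_intervals(chrom))

    def total_mappable(self) -> int:
        return sum(self.mappable_length(c) for c in self.names)

    # -- constructors ----------------------------------------------------
    @classmethod
    def male_hg19(cls) -> "GenomeModel":
        """Male hg19 genome: autosomes at copy 2, X and Y at copy 1, Y PARs masked."""
        chroms = []
        for name, length in HG19_CHROM_LENGTHS.items():
            baseline = 1 if name in ("chrX", "chrY") else 2
            chroms.append(Chromosome(name, length, baseline))
        return cls(chroms, {"chrY": list(_Y_PAR)})


class CopyNumberStateMap:
    """Non-overlapping tumour copy-number events on a genome.

    Regions not covered by an event carry the chromosome's baseline copy
    number.
    """

    def __init__(self, events: Iterable[CopyNumberEvent] = ()) -> None:
        self.events: list[CopyNumberEvent] = sorted(
            events, key=lambda ev: (ev.chrom, ev.start)
        )
        by_chrom: dict[str, list[CopyNumberEvent]] = {}
        for ev in self.events:
            by_chrom.setdefault(ev.chrom, []).append(ev)
        for chrom, evs in by_chrom.items():
            for a, b in zip(evs, evs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping events on {chrom}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}"
                    )
        self._by_chrom = by_chrom

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def events_on(self, chrom: str) -> list[CopyNumberEvent]:
        return self._by_chrom.get(chrom, [])

    def validate_against(self, genome: GenomeModel) -> None:
        for ev in self.events:
            if ev.chrom not in genome:
                raise ValueError(f"event on unknown chromosome {ev.chrom}")
            if ev.end > genome.length(ev.chrom):
                raise ValueError(
                    f"event {ev.chrom}:{ev.start}-{ev.end} outside chromosome bounds"
                )

    def with_event(self, event: CopyNumberEvent) -> "CopyNumberStateMap":
        return CopyNumberStateMap(self.events + [event])

    def without_event(self, event: CopyNumberEvent) -> "CopyNumberStateMap":
        if event not in self.events:
            raise ValueError(
                f"cannot remove absent event {event.chrom}:{event.start}-{event.end}"
            )
        kept = [ev for ev in self.events if ev != event]
        return CopyNumberStateMap(kept)


def _merge_intervals(ivls: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivls = sorted(ivls)
    out: list[tuple[int, int]] = []
    for s, e in ivls:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out
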