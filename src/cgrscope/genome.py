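"""Reference genome model: chromosome names, lengths and ordering.

The default genome is a mouse-scale model (19 autosomes + X, all acrocentric,
approximate mm39 lengths). Coordinates everywhere in this package are 0-based,
half-open.
"""

from __future__ import annotations

from collections.abc import Iterator, Mapping

__all__ = ["Genome", "default_mouse_genome", "chrom_sort_key"]

# Approximate mm39 chromosome lengths (bp).
_MOUSE_LENGTHS = {
    "chr1": 195_154_279,
    "chr2": 181_755_017,
    "chr3": 159_745_316,
    "chr4": 156_860_686,
    "chr5": 151_758_149,
    "chr6": 149_588_044,
    "chr7": 144_995_196,
    "chr8": 130_127_694,
    "chr9": 124_359_700,
    "chr10": 130_530_862,
    "chr11": 121_973_369,
    "chr12": 120_092_757,
    "chr13": 120_883_175,
    "chr14": 125_139_656,
    "chr15": 104_073_951,
    "chr16": 98_008_968,
    "chr17": 95_294_699,
    "chr18": 90_720_763,
    "chr19": 61_420_004,
    "chrX": 169_476_592,
}

_ALIAS_SUFFIX_ORDER = {"X": 100, "Y": 101, "M": 102, "MT": 102}


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural ordering: chr1 < chr2 < ... < chr19 < chrX < chrY < chrM."""
    name = chrom[3:] if chrom.startswith("chr") else chrom
    if name.isdigit():
        return (int(name), "")
    return (_ALIAS_SUFFIX_ORDER.get(name.upper(), 999), name)


def normalize_chrom(chrom: str, aliases: Mapping[str, str] | None = None) -> str:
    """Normalize a chromosome name to the "chr"-prefixed convention."""
    if aliases and chrom in aliases:
        return aliases[chrom]
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


class Genome:
    """Ordered chromosome-length table.

    Parameters
    ----------
    lengths:
        Mapping of chromosome name to length in bp. Order is normalized to
        the natural chromosome order.
    """

    def __init__(self, lengths: Mapping[str, int]):
        items = sorted(lengths.items(), key=lambda kv: chrom_sort_key(kv[0]))
        for chrom, length in items:
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        self._lengths: dict[str, int] = dict(items)
        self._order: dict[str, int] = {c: i for i, c in enumerate(self._lengths)}

    @property
    def chromosomes(self) -> list[str]:
        return list(self._lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome") from None

    def order(self, chrom: str) -> int:
        """Index of ``chrom`` in the genome ordering (for canonical sorting)."""
        try:
            return self._order[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome") from None

    def autosomes_and_x(self) -> list[str]:
        """Chromosomes used for burden metrics: autosomes plus X, never Y."""
        out = []
        for c in self._lengths:
            name = c[3:] if c.startswith("chr") else c
            if name.isdigit() or name.upper() == "X":
                out.append(c)
        return out

    def total_length(self) -> int:
        return sum(self._lengths.values())


def default_mouse_genome() -> Genome:
    """Mouse-scale default genome (19 autosomes + X)."""
    return Genome(_MOUSE_LENGTHS)
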