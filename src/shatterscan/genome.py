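"""Genome coordinate model: chromosome names, lengths and centromere intervals.

All coordinates package-wide are 0-based half-open. Chromosome names are
normalized by stripping a leading ``chr`` prefix, so ``chr5`` and ``5``
refer to the same chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence


def normalize_chrom(name: str) -> str:
    """Strip a leading 'chr' prefix (case-insensitive)."""
    name = str(name).strip()
    if name.lower().startswith("chr"):
        return name[3:]
    return name


class GenomeValidationError(ValueError):
    """Raised when coordinates or annotations violate the genome model."""


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosomes with lengths and optional centromere intervals.

    Parameters
    ----------
    chromosomes
        Chromosome names in the order they should be reported.
    lengths
        Chromosome length in base pairs, one entry per chromosome.
    centromeres
        Optional mapping chromosome -> (start, end) centromere interval,
        0-based half-open, contained in ``[0, length)``.
    """

    chromosomes: tuple[str, ...]
    lengths: Mapping[str, int]
    centromeres: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.chromosomes)) != len(self.chromosomes):
            raise GenomeValidationError("duplicate chromosome names")
        for c in self.chromosomes:
            if c not in self.lengths:
                raise GenomeValidationError(f"no length for chromosome {c!r}")
            if int(self.lengths[c]) <= 0:
                raise GenomeValidationError(f"non-positive length for {c!r}")
        for c, (s, e) in self.centromeres.items():
            if c not in self.lengths:
                raise GenomeValidationError(f"centromere on unknown chromosome {c!r}")
            if not (0 <= s < e <= self.lengths[c]):
                raise GenomeValidationError(
                    f"centromere ({s}, {e}) outside chromosome {c!r}"
                )

    def __contains__(self, chrom: str) -> bool:
        return normalize_chrom(chrom) in self.lengths

    def length(self, chrom: str) -> int:
        c = normalize_chrom(chrom)
        try:
            return int(self.lengths[c])
        except KeyError:
            raise GenomeValidationError(f"unknown chromosome {chrom!r}") from None

    def centromere(self, chrom: str) -> tuple[int, int] | None:
        return self.centromeres.get(normalize_chrom(chrom))

    def check_position(self, chrom: str, pos: int) -> None:
        if not 0 <= pos <= self.length(chrom):
            raise GenomeValidationError(
                f"position {pos} outside chromosome {chrom} "
                f"(length {self.length(chrom)})"
            )

    def permutation_pool(self) -> list[str]:
        """Chromosomes eligible for null-region resampling: autosomes + X.

        Y and mitochondrial contigs are excluded.
        """
        return [
            c for c in self.chromosomes
            if c.upper() not in {"Y", "M", "MT"}
        ]


# GRCh37 chromosome lengths and centromere intervals (UCSC gap table).
_GRCH37_LENGTHS = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566, "X": 155270560, "Y": 59373566,
}

_GRCH37_CENTROMERES = {
    "1": (121535434, 124535434), "2": (92326171, 95326171),
    "3": (90504854, 93504854), "4": (49660117, 52660117),
    "5": (46405641, 49405641), "6": (58830166, 61830166),
    "7": (58054331, 61054331), "8": (43838887, 46838887),
    "9": (47367679, 50367679), "10": (39254935, 42254935),
    "11": (51644205, 54644205), "12": (34856694, 37856694),
    "13": (16000000, 19000000), "14": (16000000, 19000000),
    "15": (17000000, 20000000), "16": (35335801, 38335801),
    "17": (22263006, 25263006), "18": (15460898, 18460898),
    "19": (24681782, 27681782), "20": (26369569, 29369569),
    "21": (11288129, 14288129), "22": (13000000, 16000000),
    "X": (58632012, 61632012), "Y": (10104553, 13104553),
}


def grch37_model() -> GenomeModel:
    """Human GRCh37 genome: chr1-22, X, Y with centromere intervals."""
    order = tuple(_GRCH37_LENGTHS)
    return GenomeModel(order, dict(_GRCH37_LENGTHS), dict(_GRCH37_CENTROMERES))


def toy_model(
    n_chromosomes: int = 3,
    length: int = 100_000_000,
    centromere_fraction: tuple[float, float] = (0.45, 0.55),
) -> GenomeModel:
    """Small synthetic genome of equal-length chromosomes, for tests/simulation."""
    names = tuple(str(i + 1) for i in range(n_chromosomes))
    lo = int(length * centromere_fraction[0])
    hi = int(length * centromere_fraction[1])
    return GenomeModel(
        names,
        {c: length for c in names},
        {c: (lo, hi) for c in names},
    )
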