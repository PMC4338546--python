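"""Reduced synthetic genome model.

The analysis operates on a desk-scale genome: ten chromosomes relevant to
TGCT biology (the i(12p) chromosome 12, the recurrently gained 7/21/22/X,
the recurrently lost Y, and several large autosomes used as neutral
background), with published hg19 chromosome and centromere coordinates
scaled down 10x.  Arm semantics (p/q, acrocentric chromosomes where the p
arm carries no usable probes) are preserved so that arm-level summaries,
isochromosome detection and chromothripsis counting behave as they would on
the full genome.

The exome probe model is a regular grid of short bins ("exons") along each
chromosome; depth-of-coverage is simulated per bin and the CNV engine never
assumes the grid is regular, only that bins are sorted and half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ArmDefinition",
    "Chromosome",
    "Genome",
    "default_genome",
    "read_arm_table",
    "write_arm_table",
]

# (name, scaled length, scaled centromere position, acrocentric)
_DEFAULT_CHROMS = [
    ("1", 24_925_062, 12_500_000, False),
    ("2", 24_319_937, 9_330_000, False),
    ("6", 17_111_507, 6_100_000, False),
    ("7", 15_913_866, 5_990_000, False),
    ("12", 13_385_190, 3_580_000, False),
    ("14", 10_734_954, 1_760_000, True),
    ("21", 4_812_990, 1_320_000, True),
    ("22", 5_130_457, 1_470_000, True),
    ("X", 15_527_056, 6_060_000, False),
    ("Y", 5_937_357, 1_250_000, True),
]

#: chromosomes carried at a single copy in a male normal genome
SEX_CHROMOSOMES = frozenset({"X", "Y"})


@dataclass(frozen=True)
class ArmDefinition:
    """One chromosome arm as a half-open interval."""

    chrom: str
    arm: str  # "p" or "q"
    start: int
    end: int
    acrocentric: bool = False

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere: int
    acrocentric: bool = False

    def arms(self) -> tuple[ArmDefinition, ArmDefinition]:
        return (
            ArmDefinition(self.name, "p", 0, self.centromere, self.acrocentric),
            ArmDefinition(self.name, "q", self.centromere, self.length, self.acrocentric),
        )


@dataclass(frozen=True)
class Genome:
    """An ordered collection of chromosomes plus the exome probe grid."""

    chromosomes: tuple[Chromosome, ...]
    bin_spacing: int = 4000
    bin_length: int = 200

    _by_name: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "_by_name", {c.name: c for c in self.chromosomes})

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def chromosome(self, name: str) -> Chromosome:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"chromosome {name!r} not in genome model") from None

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def size_bp(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def arms(self) -> list[ArmDefinition]:
        out: list[ArmDefinition] = []
        for c in self.chromosomes:
            out.extend(c.arms())
        return out

    def subset(self, names: list[str]) -> "Genome":
        """Genome restricted to the given chromosomes (order preserved)."""
        missing = [n for n in names if n not in self._by_name]
        if missing:
            raise KeyError(f"chromosomes not in genome model: {missing}")
        return Genome(
            tuple(c for c in self.chromosomes if c.name in set(names)),
            bin_spacing=self.bin_spacing,
            bin_length=self.bin_length,
        )

    def bin_grid(self) -> pd.DataFrame:
        """Exome probe bins as a BED-convention (0-based half-open) frame."""
        frames = []
        for c in self.chromosomes:
            starts = np.arange(0, c.length - self.bin_length, self.bin_spacing)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": c.name,
                        "start": starts,
                        "end": starts + self.bin_length,
                    }
                )
            )
        grid = pd.concat(frames, ignore_index=True)
        grid["chrom"] = grid["chrom"].astype(str)
        return grid

    def arm_table(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": a.chrom,
                "arm": a.arm,
                "start": a.start,
                "end": a.end,
                "acrocentric": int(a.acrocentric),
            }
            for a in self.arms()
        ]
        return pd.DataFrame(rows)


def default_genome(chromosomes: list[str] | None = None, *, bin_spacing: int = 4000,
                   bin_length: int = 200) -> Genome:
    """The bundled reduced genome, optionally restricted to a chromosome subset."""
    genome = Genome(
        tuple(Chromosome(n, ln, cen, acro) for n, ln, cen, acro in _DEFAULT_CHROMS),
        bin_spacing=bin_spacing,
        bin_length=bin_length,
    )
    if chromosomes is not None:
        genome = genome.subset(chromosomes)
    return genome


def write_arm_table(genome: Genome, path) -> None:
    genome.arm_table().to_csv(path, sep="\t", index=False)


def read_arm_table(path) -> list[ArmDefinition]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        ArmDefinition(r.chrom, r.arm, int(r.start), int(r.end), bool(r.acrocentric))
        for r in df.itertuples()
    ]
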