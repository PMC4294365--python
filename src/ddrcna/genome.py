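"""Toy genome model: chromosomes, assembly gaps and a merged gene annotation.

Coordinates are 0-based, half-open (BED convention) throughout.  The default
genome is a deliberately small caricature of the human autosomes: 22
chromosomes, a centromere and two telomeric gaps per chromosome, and the six
DNA-damage-response (DDR) sensor genes — MRE11A, RAD50, NBN, ATM, ATR,
PRKDC — placed on distinct chromosomes so that per-gene chromosome-excluded
statistics are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError

#: the six DDR sensor genes (MRN complex + PI3K-like kinases)
DDR_GENES = ("MRE11A", "RAD50", "NBN", "ATM", "ATR", "PRKDC")

# home chromosome per gene; real assignments kept where they are unique
# (NBN 8, MRE11A 11, RAD50 5, ATR 3), the rest spread out so every DDR gene
# sits alone on its chromosome.
_DEFAULT_GENE_CHROMS = {
    "ATR": "chr3",
    "RAD50": "chr5",
    "NBN": "chr8",
    "ATM": "chr10",
    "MRE11A": "chr11",
    "PRKDC": "chr16",
    # two non-DDR companions used by the expression analyses
    "MYC": "chr8",
    "KPNA2": "chr17",
}


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome sizes, gap intervals and a merged gene annotation.

    Attributes
    ----------
    chromosomes : list of (name, length)
    gaps : list of (chrom, start, end, kind) with kind in {centromere, telomere}
    genes : list of (chrom, start, end, symbol); intervals on one chromosome
        are non-overlapping (annotation already merged per symbol).
    """

    chromosomes: list[tuple[str, int]]
    gaps: list[tuple[str, int, int, str]]
    genes: list[tuple[str, int, int, str]]

    def __post_init__(self) -> None:
        sizes = dict(self.chromosomes)
        for chrom, start, end, kind in self.gaps:
            if kind not in ("centromere", "telomere"):
                raise ConfigurationError(f"unknown gap kind {kind!r}")
            self._check_interval(sizes, chrom, start, end, f"gap {kind}")
        seen: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, symbol in self.genes:
            self._check_interval(sizes, chrom, start, end, f"gene {symbol}")
            seen.setdefault(chrom, []).append((start, end))
        for chrom, ivals in seen.items():
            ivals.sort()
            for (s0, e0), (s1, e1) in zip(ivals, ivals[1:]):
                if s1 < e0:
                    raise ConfigurationError(
                        f"overlapping gene intervals on {chrom}: "
                        f"[{s0},{e0}) and [{s1},{e1})"
                    )

    @staticmethod
    def _check_interval(sizes, chrom, start, end, what) -> None:
        if chrom not in sizes:
            raise ConfigurationError(f"{what}: unknown chromosome {chrom!r}")
        if not (0 <= start < end <= sizes[chrom]):
            raise ConfigurationError(
                f"{what}: interval [{start},{end}) outside {chrom} "
                f"(length {sizes[chrom]})"
            )

    # ---- convenience views -------------------------------------------------

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_size(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def gene_chrom_map(self) -> dict[str, str]:
        return {symbol: chrom for chrom, _, _, symbol in self.genes}

    def gene_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.genes, columns=["chrom", "start", "end", "symbol"]
        ).sort_values(["chrom", "start"], ignore_index=True)

    def gap_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.gaps, columns=["chrom", "start", "end", "kind"]
        ).sort_values(["chrom", "start"], ignore_index=True)

    # ---- writers (BED / chrom.sizes) ---------------------------------------

    def write_genes_bed(self, path) -> None:
        self.gene_table()[["chrom", "start", "end", "symbol"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    def write_gaps_bed(self, path) -> None:
        self.gap_table()[["chrom", "start", "end", "kind"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    def write_chrom_sizes(self, path) -> None:
        pd.DataFrame(self.chromosomes).to_csv(
            path, sep="\t", header=False, index=False
        )


def generate_genome(
    n_chromosomes: int = 22,
    chrom_length: int = 1_000_000,
    gene_length: int = 100_000,
    gene_offset: int = 200_000,
    telomere_length: int = 10_000,
    centromere: tuple[int, int] = (480_000, 520_000),
    gene_chroms: dict[str, str] | None = None,
) -> GenomeSpec:
    """Build a toy multi-chromosome genome with gaps and DDR gene placements.

    Every chromosome gets two telomeric gaps and one centromere; each gene is
    a single ``gene_length`` interval starting at ``gene_offset`` on its home
    chromosome (a second gene on the same chromosome is shifted right so the
    annotation stays non-overlapping).
    """
    if n_chromosomes < 2:
        raise ConfigurationError("need at least 2 chromosomes")
    gene_chroms = dict(_DEFAULT_GENE_CHROMS if gene_chroms is None else gene_chroms)
    chroms = [(f"chr{i}", chrom_length) for i in range(1, n_chromosomes + 1)]
    names = {c for c, _ in chroms}
    missing = {g: c for g, c in gene_chroms.items() if c not in names}
    if missing:
        raise ConfigurationError(
            f"gene home chromosomes not in genome: {sorted(missing.items())}"
        )

    gaps: list[tuple[str, int, int, str]] = []
    for name, length in chroms:
        gaps.append((name, 0, telomere_length, "telomere"))
        gaps.append((name, length - telomere_length, length, "telomere"))
        gaps.append((name, centromere[0], centromere[1], "centromere"))

    genes: list[tuple[str, int, int, str]] = []
    used: dict[str, int] = {}
    for symbol, chrom in sorted(gene_chroms.items()):
        slot = used.get(chrom, 0)
        # slide subsequent genes on a shared chromosome past the centromere
        start = gene_offset if slot == 0 else centromere[1] + gene_offset
        end = start + gene_length
        if end > chrom_length - telomere_length:
            raise ConfigurationError(
                f"gene {symbol} does not fit on {chrom} (length {chrom_length})"
            )
        used[chrom] = slot + 1
        genes.append((chrom, start, end, symbol))

    return GenomeSpec(chromosomes=chroms, gaps=gaps, genes=genes)


def default_genome() -> GenomeSpec:
    """The genome used by the shipped scenarios."""
    return generate_genome()
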