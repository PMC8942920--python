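"""Closed-form partition of transposable elements (TEs) between
chromocenters and euchromatin.

The RHF measures the fraction of genomic DNA residing in chromocenters
(CCs). Since the long tandem repeats — the centromeric 180-bp satellite
arrays (8.76 Mb) and the 45S rDNA NOR arrays (7.5 Mb) — are stable CC
components, the TE complement found in CCs follows from the DNA bookkeeping

    te_in_cc = (RHF × G − T) / (f × G)

with G the genome size (Mb), T the tandem-repeat total (Mb) and f the TE
fraction of the genome (0.10). The complement ``te_in_eu = 1 − te_in_cc``.
Because genome-size estimates for Arabidopsis differ between studies, four
values are carried: 125, 157, 191 and 211 Mb. 5S rDNA (~0.5 Mb) is excluded
as it frequently lies outside chromocenters.

Out-of-range values are biologically meaningful and flagged rather than
clipped: te_in_cc < 0 implies that part of the tandem repeats themselves
must be euchromatic (or the genome-size estimate is too small);
te_in_cc > 1 implies that CCs hold more DNA than all repeats combined, i.e.
gene-rich regions are also packaged in CCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError

GENOME_SIZE_ESTIMATES_MB = (125.0, 157.0, 191.0, 211.0)
CENTROMERIC_180BP_MB = 8.76   # pachytene FISH estimate
NOR_45S_MB = 7.5              # CHEF gel estimate
TANDEM_TOTAL_MB = CENTROMERIC_180BP_MB + NOR_45S_MB  # 16.3

FLAG_NOMINAL = "NOMINAL"
FLAG_TANDEM_PARTLY_EUCHROMATIC = "TANDEM_PARTLY_EUCHROMATIC"
FLAG_GENES_IN_CC = "GENES_IN_CC"


@dataclass(frozen=True)
class GenomeModel:
    genome_size: float = 211.0             # Mb
    tandem_total: float = TANDEM_TOTAL_MB  # Mb
    te_fraction_of_genome: float = 0.10

    def __post_init__(self) -> None:
        if not (self.genome_size > self.tandem_total > 0):
            raise ConfigurationError(
                "genome_size must exceed tandem_total and both must be positive"
            )
        if not (0 < self.te_fraction_of_genome < 1):
            raise ConfigurationError("te_fraction_of_genome must lie in (0, 1)")


@dataclass(frozen=True)
class RepeatPartition:
    rhf: float
    genome_size: float
    te_in_cc: float       # may legitimately be < 0 or > 1
    te_in_eu: float       # always 1 - te_in_cc
    flags: frozenset[str] = frozenset({FLAG_NOMINAL})


def te_fraction_in_cc(rhf: float, gm: GenomeModel | None = None) -> RepeatPartition:
    """Partition the TE complement given a measured RHF.

    te_in_cc = (rhf·G − T) / (f·G); te_in_eu is its exact complement.
    """
    gm = gm or GenomeModel()
    if not (0.0 <= rhf <= 1.0):
        raise ValueError(f"rhf must lie in [0, 1], got {rhf}")
    g, t, f = gm.genome_size, gm.tandem_total, gm.te_fraction_of_genome
    te_in_cc = (rhf * g - t) / (f * g)
    if te_in_cc < 0:
        flags = frozenset({FLAG_TANDEM_PARTLY_EUCHROMATIC})
    elif te_in_cc > 1:
        flags = frozenset({FLAG_GENES_IN_CC})
    else:
        flags = frozenset({FLAG_NOMINAL})
    return RepeatPartition(
        rhf=rhf, genome_size=g, te_in_cc=te_in_cc, te_in_eu=1.0 - te_in_cc, flags=flags
    )


def rhf_bounds(gm: GenomeModel | None = None) -> tuple[float, float]:
    """RHF values at which the partition hits its physical edges.

    Lower bound T/G: all TEs are euchromatic (te_in_cc = 0).
    Upper bound (T + f·G)/G: all repeats, tandem arrays and TEs, are in CCs
    (te_in_cc = 1); above it, gene-rich DNA must also reside in CCs.
    """
    gm = gm or GenomeModel()
    g, t, f = gm.genome_size, gm.tandem_total, gm.te_fraction_of_genome
    return t / g, (t + f * g) / g


def partition_table(
    rhf_by_group: dict[str, float],
    genome_sizes: tuple[float, ...] = GENOME_SIZE_ESTIMATES_MB,
    tandem_total: float = TANDEM_TOTAL_MB,
    te_fraction_of_genome: float = 0.10,
) -> pd.DataFrame:
    """Group × genome-size grid of TE partitions (one row per combination).

    Raw unrounded values are kept alongside report-rounded columns
    (fractions to 2 d.p., percentages to whole percent).
    """
    rows = []
    for group, rhf in rhf_by_group.items():
        for g in genome_sizes:
            gm = GenomeModel(
                genome_size=g, tandem_total=tandem_total,
                te_fraction_of_genome=te_fraction_of_genome,
            )
            p = te_fraction_in_cc(rhf, gm)
            rows.append(
                {
                    "group": group,
                    "genome_size_mb": g,
                    "rhf": rhf,
                    "te_in_cc": p.te_in_cc,
                    "te_in_eu": p.te_in_eu,
                    "te_in_cc_2dp": round(p.te_in_cc, 2),
                    "te_in_eu_pct": round(100.0 * p.te_in_eu),
                    "flags": ";".join(sorted(p.flags)),
                }
            )
    columns = [
        "group", "genome_size_mb", "rhf", "te_in_cc", "te_in_eu",
        "te_in_cc_2dp", "te_in_eu_pct", "flags",
    ]
    return pd.DataFrame(rows, columns=columns)
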