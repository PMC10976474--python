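"""Order-of-magnitude phosphate release from phage DNA replication.

During replication, DNA polymerase incorporates dNTPs and releases
pyrophosphate, i.e. two phosphate molecules per nucleotide added.  For an
infected cell producing ``burst_size`` progeny of ``genome_length``
nucleotides each, the phosphate liberated by polymerase activity alone is

    total = burst_size × genome_length × strand_factor × phosphates_per_nt

with ``strand_factor`` 2 when the genome length is read as one duplex strand
and both strands are synthesized de novo (off by default: the default reads
``genome_length`` as the nucleotide count per progeny genome).  Defaults —
12 progeny per cell under phosphate starvation, a 200 kb genome, 2 phosphates
per nucleotide — give 4.8e6 molecules, order of magnitude 10^6.  Either
strand convention floors to 10^6, which is why the result is reported as an
order of magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import ConfigurationError

DEFAULT_BURST_SIZE = 12
DEFAULT_GENOME_LENGTH = 200_000
DEFAULT_PHOSPHATES_PER_NT = 2


@dataclass(frozen=True)
class BudgetInput:
    burst_size: float = DEFAULT_BURST_SIZE
    genome_length: int = DEFAULT_GENOME_LENGTH
    phosphates_per_nt: int = DEFAULT_PHOSPHATES_PER_NT
    count_both_strands: bool = False

    def __post_init__(self) -> None:
        if self.burst_size <= 0 or self.genome_length <= 0 or self.phosphates_per_nt <= 0:
            raise ConfigurationError("all budget inputs must be positive")


@dataclass(frozen=True)
class BudgetResult:
    total_phosphate: float
    order_of_magnitude: int
    uptake_equivalent_hours: float | None = None


def phosphate_released(
    inputs: BudgetInput | None = None,
    *,
    uptake_rate: float | None = None,
) -> BudgetResult:
    """Phosphate molecules released per infected cell, with floor(log10) order.

    ``uptake_rate`` (molecules per cell per hour), when given, converts the
    total into the equivalent hours of cellular phosphate uptake.
    """
    inputs = inputs or BudgetInput()
    total = (
        inputs.burst_size
        * inputs.genome_length
        * (2 if inputs.count_both_strands else 1)
        * inputs.phosphates_per_nt
    )
    order = math.floor(math.log10(total))
    hours = None
    if uptake_rate is not None:
        if uptake_rate <= 0:
            raise ConfigurationError("uptake_rate must be positive")
        hours = total / uptake_rate
    return BudgetResult(float(total), order, hours)
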