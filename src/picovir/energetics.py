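"""Direct energetic cost of dsDNA viral genome replication.

The cost of synthesising one double-stranded genome is approximated as

    E_rep = 2 * L_g * (e_d + e_p)

where ``L_g`` is the single-strand genome length in bases (the factor 2
carries the double-strandedness), ``e_d`` the ATP-equivalent cost of
synthesising one DNA precursor from central metabolites, and ``e_p`` the
ATP-equivalent cost of chain elongation per base.  Transcription,
translation and indirect (opportunity) costs are deliberately excluded.

All arithmetic is exact when inputs are integers.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["GenomeCostParams", "replication_cost", "cost_difference"]

#: ATP-equivalent hydrolysis events per nucleotide for precursor synthesis.
DEFAULT_PRECURSOR_COST = 11
#: ATP-equivalent hydrolysis events per nucleotide for chain elongation.
DEFAULT_ELONGATION_COST = 2


@dataclass(frozen=True)
class GenomeCostParams:
    """Parameters of the replication-cost model.

    Parameters
    ----------
    genome_length : int or float
        Single-strand length of the dsDNA genome, in bases.
    precursor_cost : int or float
        ATP-equivalents per nucleotide for precursor (dNTP) synthesis.
    elongation_cost : int or float
        ATP-equivalents per nucleotide for polymerisation.
    """

    genome_length: float
    precursor_cost: float = DEFAULT_PRECURSOR_COST
    elongation_cost: float = DEFAULT_ELONGATION_COST

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.precursor_cost < 0 or self.elongation_cost < 0:
            raise ValueError("per-nucleotide costs must be non-negative")


def replication_cost(params: GenomeCostParams) -> float:
    """ATP-equivalents required to replicate one dsDNA genome."""
    return 2 * params.genome_length * (params.precursor_cost + params.elongation_cost)


def cost_difference(
    length_a: float,
    length_b: float,
    precursor_cost: float = DEFAULT_PRECURSOR_COST,
    elongation_cost: float = DEFAULT_ELONGATION_COST,
) -> float:
    """Absolute difference in replication cost between two genome lengths.

    Depends only on ``|length_a - length_b|`` (translation invariance).
    """
    cost_a = replication_cost(GenomeCostParams(length_a, precursor_cost, elongation_cost))
    cost_b = replication_cost(GenomeCostParams(length_b, precursor_cost, elongation_cost))
    return abs(cost_a - cost_b)
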