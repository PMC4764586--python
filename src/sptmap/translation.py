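"""Back-of-envelope translation kinetics.

Used to compare motion-state lifetimes against the time scale of
synthesizing one protein: at a ribosome elongation rate of 5.6 amino
acids per second, one β-actin molecule (375 aa) takes ~67 s — orders of
magnitude longer than the second-scale slow-state dwell times, so a
slow-motion state cannot correspond to a full translation cycle.
"""

ACTB_PROTEIN_LENGTH_AA = 375  # mature mouse β-actin
DEFAULT_ELONGATION_RATE = 5.6  # amino acids per second


def translation_time(
    protein_length_aa: int = ACTB_PROTEIN_LENGTH_AA,
    elongation_rate_aa_per_s: float = DEFAULT_ELONGATION_RATE,
) -> float:
    """Seconds for one ribosome to elongate a protein of the given length."""
    if protein_length_aa <= 0 or elongation_rate_aa_per_s <= 0:
        raise ValueError("length and rate must be positive")
    return protein_length_aa / elongation_rate_aa_per_s
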