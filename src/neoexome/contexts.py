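"""Canonical 96-class trinucleotide substitution taxonomy.

Classes follow the standard convention: six pyrimidine-centred substitution
types (C>A, C>G, C>T, T>A, T>C, T>G) crossed with the 16 combinations of 5'
and 3' flanking bases, ordered substitution-major then 5' then 3' flank.
"""

from __future__ import annotations

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SBS96_CLASSES: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)
CLASS_INDEX = {label: i for i, label in enumerate(SBS96_CLASSES)}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sbs96_class(ref: str, alt: str, context: str) -> str:
    """Canonical class label for a substitution in its trinucleotide context.

    `context` is the reference 3-mer centred on the variant; purine-reference
    calls are reverse-complemented so the middle base is a pyrimidine.
    """
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not centre on ref {ref!r}")
    if ref in "AG":
        context = revcomp(context)
        ref = context[1]
        alt = alt.translate(_COMPLEMENT)
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    if label not in CLASS_INDEX:
        raise ValueError(f"not a substitution class: {label!r}")
    return label


def class_components(label: str) -> tuple[str, str, str]:
    """(ref, alt, pyrimidine-strand context) for a canonical class label."""
    five, rest = label.split("[")
    sub, three = rest.split("]")
    ref, alt = sub.split(">")
    return ref, alt, f"{five}{ref}{three}"
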