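"""96-channel substitution conventions (COSMIC ordering).

Single-base substitutions are represented in the pyrimidine context: a
mutated purine is reverse-complemented so every mutation falls into one of
six classes (C>A, C>G, C>T, T>A, T>C, T>G), each split by the 16 possible
5'/3' flanking-base combinations, giving 96 channels.  Channel labels look
like ``A[C>A]A``.  Within each class, contexts are ordered by 5' base then
3' base, alphabetically.
"""

from __future__ import annotations

BASES = "ACGT"
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

CHANNELS_96 = tuple(
    f"{five}[{cls}]{three}"
    for cls in SUBSTITUTION_CLASSES
    for five in BASES
    for three in BASES
)

CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS_96)}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def channel_of(ref: str, alt: str, context: str) -> str:
    """Map a substitution to its pyrimidine-collapsed channel label.

    ``context`` is the 3-mer reference context centred on the mutated base;
    its middle base must equal ``ref``.
    """
    if len(context) != 3 or context[1] != ref:
        raise ValueError(
            f"context {context!r} middle base does not match ref {ref!r}"
        )
    if ref == alt:
        raise ValueError(f"ref and alt are both {ref!r}")
    if ref in PURINES:
        ref = reverse_complement(ref)
        alt = reverse_complement(alt)
        context = reverse_complement(context)
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    if label not in CHANNEL_INDEX:
        raise ValueError(f"invalid channel {label!r}")
    return label


def channel_mutation(label: str) -> tuple[str, str, str]:
    """Inverse of :func:`channel_of`: channel label -> (ref, alt, context)."""
    if label not in CHANNEL_INDEX:
        raise ValueError(f"unknown channel label {label!r}")
    five, rest = label.split("[")
    cls, three = rest.split("]")
    ref, alt = cls.split(">")
    return ref, alt, f"{five}{ref}{three}"
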