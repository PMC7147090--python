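"""The 96 pyrimidine-centric trinucleotide substitution channels.

Single-base substitutions are reported on the strand whose reference base is a
pyrimidine (C or T); purine-reference substitutions are reverse-complemented.
Each channel label has the form ``F[R>A]T`` where ``R>A`` is one of the six
pyrimidine substitutions and ``F``/``T`` are the 5' and 3' flanking bases, for
6 x 4 x 4 = 96 channels in the conventional catalog order (substitution-major,
then 5' flank, then 3' flank).
"""

from __future__ import annotations

BASES = "ACGT"
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Canonical, ordered tuple of the 96 channel labels.
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

CHANNEL_INDEX: dict[str, int] = {c: i for i, c in enumerate(CHANNELS)}


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"unresolvable context: non-ACGT base {exc.args[0]!r}") from None


def channel_of(ref_allele: str, alt_allele: str, context3: str) -> str:
    """Map a single-base substitution with its 3-mer context to its channel label.

    Parameters
    ----------
    ref_allele, alt_allele
        Single uppercase bases, distinct.
    context3
        3-mer reference context centered on the substituted base; its middle
        base must equal ``ref_allele``.

    Purine-reference substitutions are folded onto the pyrimidine strand by
    reverse-complementing both alleles and the context.
    """
    ref = ref_allele.upper()
    alt = alt_allele.upper()
    ctx = context3.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not a single-base substitution: {ref_allele}>{alt_allele}")
    for base in (ref, alt, *ctx):
        if base not in _COMPLEMENT:
            raise ValueError(f"unresolvable context: non-ACGT base {base!r}")
    if len(ctx) != 3 or ctx[1] != ref:
        raise ValueError(f"context {context3!r} is not centered on ref allele {ref!r}")
    if ref in "AG":
        ctx = revcomp(ctx)
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
    label = f"{ctx[0]}[{ref}>{alt}]{ctx[2]}"
    assert label in CHANNEL_INDEX
    return label


def parse_channel(label: str) -> tuple[str, str, str]:
    """Split a channel label into (ref, alt, context3). Inverse of the label format."""
    if label not in CHANNEL_INDEX:
        raise ValueError(f"unknown channel label {label!r}")
    five, rest = label.split("[")
    sub, three = rest.split("]")
    ref, alt = sub.split(">")
    return ref, alt, five + ref + three
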