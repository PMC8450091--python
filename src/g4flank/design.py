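"""Oligonucleotide library design by loop permutation.

Model G-quadruplex sequences follow the template ``5'-GGG Ta GGG Tb GGG Tc GGG-3'``
where ``a``, ``b`` and ``c`` are the lengths (in nucleotides) of the first (5'),
central and third (3') loops.  Flanking nucleotides may be appended at either
end.  Designs are named with a positional three-digit code, optionally prefixed
by a flank scheme:

* ``136``       — loops (1, 3, 6), no flanks
* ``5'T2-136``  — two thymines at the 5' end
* ``3'T2-136``  — two thymines at the 3' end
* ``DT2-136``   — two thymines at both ends

A *group* is the set of sequences obtained by permuting a fixed multiset of
loop lengths over the three loop positions (6, 3 or 1 members).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "OligoDesign",
    "GroupSpec",
    "FLANK_SCHEMES",
    "parse_name",
    "parse_flank_scheme",
    "make_name",
    "render_sequence",
    "enumerate_group",
    "shortest_loop_category",
    "designs_to_records",
    "write_fasta",
]

_VALID_BASES = frozenset("ACGT")

_NAME_RE = re.compile(r"^(?:(5'T|3'T|DT)(\d+)-)?(\d{3})$")

#: Canonical flank-scheme tokens: WO (without), 5'Tn, 3'Tn, DTn.
FLANK_SCHEMES = ("WO", "5'T", "3'T", "DT")


class NameError_(ValueError):
    """Raised for names outside the library grammar."""


@dataclass(frozen=True)
class OligoDesign:
    """A single library member: loop lengths, flanks and G-tract length.

    ``loop_base`` fills the loops (thymine by default, so loop/flank
    interactions are minimal); ``phosphate5`` is bookkeeping for a 5'-terminal
    phosphate on an otherwise unflanked 5' end and does not affect rendering.
    """

    name: str
    loops: tuple[int, int, int]
    flank5: str = ""
    flank3: str = ""
    g_run: int = 3
    loop_base: str = "T"
    phosphate5: bool = False

    def __post_init__(self) -> None:
        if len(self.loops) != 3 or any(
            not isinstance(n, int) or n < 1 for n in self.loops
        ):
            raise ValueError(f"loops must be three positive integers, got {self.loops!r}")
        if self.g_run < 2:
            raise ValueError(f"g_run must be >= 2, got {self.g_run}")
        for label, flank in (("flank5", self.flank5), ("flank3", self.flank3)):
            if not set(flank) <= _VALID_BASES:
                raise ValueError(f"{label} contains non-ACGT characters: {flank!r}")
        if self.loop_base not in _VALID_BASES:
            raise ValueError(f"loop_base must be one of A/C/G/T, got {self.loop_base!r}")

    @property
    def sequence(self) -> str:
        return render_sequence(self)

    def __len__(self) -> int:
        return 4 * self.g_run + sum(self.loops) + len(self.flank5) + len(self.flank3)


@dataclass(frozen=True)
class GroupSpec:
    """A loop-permutation group: an unordered loop multiset plus a flank scheme.

    ``flank_scheme`` is one of ``WO``, ``5'T<n>``, ``3'T<n>``, ``DT<n>``.
    """

    loop_multiset: tuple[int, ...]
    flank_scheme: str = "WO"

    def __post_init__(self) -> None:
        object.__setattr__(self, "loop_multiset", tuple(sorted(self.loop_multiset)))
        if len(self.loop_multiset) != 3 or any(n < 1 for n in self.loop_multiset):
            raise ValueError(
                f"loop_multiset must hold three positive integers, got {self.loop_multiset!r}"
            )
        parse_flank_scheme(self.flank_scheme)  # validates

    @property
    def group_id(self) -> str:
        digits = "".join(str(n) for n in self.loop_multiset)
        return digits if self.flank_scheme == "WO" else f"{self.flank_scheme}-{digits}"

    def members(self) -> list[OligoDesign]:
        return enumerate_group(self.loop_multiset, self.flank_scheme)


def parse_flank_scheme(scheme: str) -> tuple[str, int]:
    """Split a scheme token into (kind, flank length); ``WO`` -> ("WO", 0)."""
    if scheme == "WO":
        return "WO", 0
    m = re.match(r"^(5'T|3'T|DT)([1-9]\d*)$", scheme)
    if m is None:
        raise NameError_(f"unknown flank scheme {scheme!r}")
    return m.group(1), int(m.group(2))


def parse_name(name: str) -> OligoDesign:
    """Parse a library name such as ``DT2-136`` into an :class:`OligoDesign`.

    Bare three-digit names mean no flanks; prefixes ``5'T<k>``, ``3'T<k>`` and
    ``DT<k>`` add ``k`` thymines at the 5' end, the 3' end, or both.
    """
    m = _NAME_RE.match(name.strip())
    if m is None:
        raise NameError_(f"name {name!r} does not match the library grammar")
    prefix, k_str, digits = m.groups()
    if prefix is not None:
        k = int(k_str)
        if k < 1:
            raise NameError_(f"flank length in {name!r} must be >= 1, got {k_str!r}")
    else:
        k = 0
    loops = tuple(int(d) for d in digits)
    if 0 in loops:
        raise NameError_(f"zero loop length in loop code {digits!r}")
    flank = "T" * k
    flank5 = flank if prefix in ("5'T", "DT") else ""
    flank3 = flank if prefix in ("3'T", "DT") else ""
    return OligoDesign(name=name.strip(), loops=loops, flank5=flank5, flank3=flank3)


def make_name(loops: tuple[int, int, int], flank_scheme: str = "WO") -> str:
    """Canonical name for a loop ordering under a flank scheme."""
    if any(not 1 <= n <= 9 for n in loops):
        raise NameError_(f"loop digits must be single-digit (1-9), got {loops!r}")
    digits = "".join(str(n) for n in loops)
    parse_flank_scheme(flank_scheme)
    return digits if flank_scheme == "WO" else f"{flank_scheme}-{digits}"


def render_sequence(design: OligoDesign) -> str:
    """Render 5'->3': flank5 + (G-tract + loop) x 3 + G-tract + flank3."""
    g = "G" * design.g_run
    a, b, c = design.loops
    t = design.loop_base
    return design.flank5 + g + t * a + g + t * b + g + t * c + g + design.flank3


def enumerate_group(
    loop_multiset: tuple[int, ...] | list[int] | set[int],
    flank_scheme: str = "WO",
) -> list[OligoDesign]:
    """All distinct loop orderings of a multiset, lexicographic in (a, b, c).

    The member count is the number of distinct permutations: 6 for three
    distinct lengths, 3 for one repeat, 1 for a constant multiset.
    """
    loops = tuple(sorted(loop_multiset))
    if len(loops) != 3 or any(n < 1 for n in loops):
        raise ValueError(f"loop multiset must hold three positive integers, got {loops!r}")
    orderings = sorted(set(itertools.permutations(loops)))
    return [parse_name(make_name(p, flank_scheme)) for p in orderings]


def shortest_loop_category(design: OligoDesign) -> str:
    """Position of a unique single-thymine shortest loop: 1bc, a1c, ab1 or none.

    ``1bc``/``a1c``/``ab1`` when exactly the first/central/third loop is the
    unique minimum and has length 1; ``none`` otherwise (no length-1 loop, or
    tied minimum).
    """
    a, b, c = design.loops
    ones = [i for i, n in enumerate((a, b, c)) if n == min(a, b, c)]
    if min(a, b, c) != 1 or len(ones) != 1:
        return "none"
    return ("1bc", "a1c", "ab1")[ones[0]]


def enumerate_loop_multisets(
    total_min: int = 7, total_max: int = 13, max_loop: int = 6, min_loop: int = 1
) -> list[tuple[int, int, int]]:
    """All loop multisets a <= b <= c within the library's length constraints.

    The model library spans loop lengths 1-6 with total loop length 7-13;
    these bounds are exposed as parameters rather than a fixed printed set.
    """
    out = []
    for a in range(min_loop, max_loop + 1):
        for b in range(a, max_loop + 1):
            for c in range(b, max_loop + 1):
                if total_min <= a + b + c <= total_max:
                    out.append((a, b, c))
    return out


def with_flank_base(design: OligoDesign, base: str) -> OligoDesign:
    """Replace the flank composition with another base, keeping lengths."""
    if base not in _VALID_BASES:
        raise ValueError(f"flank base must be one of A/C/G/T, got {base!r}")
    return replace(
        design,
        flank5=base * len(design.flank5),
        flank3=base * len(design.flank3),
    )


def designs_to_records(designs: list[OligoDesign]) -> list[SeqRecord]:
    return [
        SeqRecord(Seq(render_sequence(d)), id=d.name, description="")
        for d in designs
    ]


def write_fasta(designs: list[OligoDesign], path) -> int:
    """Write rendered sequences as FASTA (name as record id); returns count."""
    from Bio import SeqIO

    records = designs_to_records(designs)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    return len(records)
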