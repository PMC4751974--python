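"""Virtual library generation from degenerate templates.

A library template is an ordered list of positions, each carrying either a
fixed residue or a set of allowed residues.  Protein-level templates are
written as a string of residue letters and user-defined wildcard symbols
(e.g. ``h`` -> {N, I} at core ``a`` positions, ``p`` -> {E, K} at the
electrostatic ``e``/``g`` positions); DNA-level templates are written as
degenerate codons over the IUPAC nucleotide ambiguity alphabet and are
collapsed to per-position residue options through the standard genetic code.

Expansion is streamed: members are yielded one at a time in stable
lexicographic order, so large templates never need the full library in
memory.  An optional composition constraint (exact residue counts at one
register class, e.g. exactly two Asn and two Ile at the four ``a``
positions) filters members during enumeration.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .heptad import CAP, STANDARD_AA, RegisteredPeptide, assign_register

__all__ = [
    "LibraryTemplate",
    "CompositionConstraint",
    "TemplateError",
    "parse_template",
    "parse_dna_template",
    "expand_template",
    "expand_degenerate_dna",
]


class TemplateError(ValueError):
    """Malformed template text or unknown wildcard symbol."""


@dataclass(frozen=True)
class LibraryTemplate:
    """Ordered per-position residue options plus register bookkeeping.

    ``positions`` holds, for every scored position, the sorted tuple of
    allowed residues.  ``cap_prefix``/``cap_suffix`` are fixed flanks added
    to every member and annotated as caps; ``start_letter`` sets the heptad
    register of the first scored position.
    """

    positions: tuple[tuple[str, ...], ...]
    mode: str = "protein"
    start_letter: str = "g"
    cap_prefix: str = ""
    cap_suffix: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("protein", "dna"):
            raise TemplateError(f"unknown template mode {self.mode!r}")
        for i, opts in enumerate(self.positions):
            if not opts:
                raise TemplateError(f"position {i + 1} has no residue options")

    @property
    def size(self) -> int:
        """Cartesian-product size of the unconstrained library."""
        n = 1
        for opts in self.positions:
            n *= len(opts)
        return n

    def register(self) -> str:
        """Register string shared by every member of the library."""
        probe = self.cap_prefix + "".join(o[0] for o in self.positions) + self.cap_suffix
        return assign_register(
            probe,
            self.start_letter,
            len(self.cap_prefix),
            len(self.cap_suffix),
            id="template",
        ).register

    def class_offsets(self, register_letter: str) -> tuple[int, ...]:
        """Indices *within the scored core* of one register class."""
        reg = self.register().strip(CAP)
        return tuple(i for i, r in enumerate(reg) if r == register_letter)


@dataclass(frozen=True)
class CompositionConstraint:
    """Exact residue counts required at one register position class."""

    register_letter: str
    residue_counts: Mapping[str, int]

    def validate_against(self, template: LibraryTemplate) -> tuple[int, ...]:
        offsets = template.class_offsets(self.register_letter)
        total = sum(self.residue_counts.values())
        if total != len(offsets):
            raise ValueError(
                f"constraint counts sum to {total} but the template has "
                f"{len(offsets)} {self.register_letter!r} positions"
            )
        return offsets

    def matches(self, core: str, offsets: tuple[int, ...]) -> bool:
        counts = Counter(core[i] for i in offsets)
        return counts == Counter(self.residue_counts)


def parse_template(
    text: str,
    symbol_table: Mapping[str, Iterable[str]],
    *,
    start_letter: str = "g",
    cap_prefix: str = "",
    cap_suffix: str = "",
) -> LibraryTemplate:
    """Parse a protein-level template string.

    Every character of ``text`` is either a wildcard defined in
    ``symbol_table`` (mapping symbol -> allowed residues) or a fixed
    standard residue.  Whitespace is ignored.
    """
    table = {s: tuple(sorted(set(opts))) for s, opts in symbol_table.items()}
    for sym, opts in table.items():
        bad = set(opts) - STANDARD_AA
        if bad:
            raise TemplateError(f"symbol {sym!r} offers non-residue option(s) {sorted(bad)}")
    positions: list[tuple[str, ...]] = []
    for ch in text:
        if ch.isspace():
            continue
        if ch in table:
            positions.append(table[ch])
        elif ch in STANDARD_AA:
            positions.append((ch,))
        else:
            raise TemplateError(f"unknown template symbol {ch!r}")
    return LibraryTemplate(
        positions=tuple(positions),
        mode="protein",
        start_letter=start_letter,
        cap_prefix=cap_prefix,
        cap_suffix=cap_suffix,
    )


def expand_template(
    template: LibraryTemplate,
    constraints: Iterable[CompositionConstraint] | CompositionConstraint | None = None,
    *,
    id_prefix: str = "lib",
) -> Iterator[RegisteredPeptide]:
    """Stream every library member, deduplicated and lexicographically ordered.

    Members are numbered in emission order, so identical inputs always yield
    byte-identical libraries.  Constraints (if any) filter members on the
    fly; an empty result is a warning, not an error.
    """
    if isinstance(constraints, CompositionConstraint):
        constraints = [constraints]
    constraints = list(constraints or [])
    checked = [(c, c.validate_against(template)) for c in constraints]
    register = template.register()
    # sorted per-position options make itertools.product lexicographic;
    # options are deduplicated sets, so members are unique by construction
    n_emitted = 0
    for combo in itertools.product(*template.positions):
        core = "".join(combo)
        if all(c.matches(core, offs) for c, offs in checked):
            seq = template.cap_prefix + core + template.cap_suffix
            yield RegisteredPeptide(
                id=f"{id_prefix}{n_emitted:05d}", sequence=seq, register=register
            )
            n_emitted += 1
    if n_emitted == 0:
        warnings.warn("library expansion produced no members", UserWarning, stacklevel=2)


# -- DNA-level templates --------------------------------------------------

_IUPAC_DNA = {k: v for k, v in ambiguous_dna_values.items() if k != "X"}


def _codon_options(codon: str) -> tuple[tuple[str, ...], bool]:
    """Residues encoded by a degenerate codon; flags stop codons.

    Brute-force expansion of the ambiguity codes followed by standard-code
    translation of every concrete codon.
    """
    for base in codon:
        if base not in _IUPAC_DNA:
            raise TemplateError(f"non-IUPAC nucleotide {base!r} in codon {codon!r}")
    residues: set[str] = set()
    has_stop = False
    for bases in itertools.product(*(_IUPAC_DNA[b] for b in codon)):
        aa = str(Seq("".join(bases)).translate())
        if aa == "*":
            has_stop = True
        else:
            residues.add(aa)
    return tuple(sorted(residues)), has_stop


def parse_dna_template(
    text: str,
    *,
    start_letter: str = "g",
    cap_prefix: str = "",
    cap_suffix: str = "",
    on_stop: str = "warn",
) -> LibraryTemplate:
    """Parse a degenerate-codon DNA template into per-position residue options.

    ``text`` length must be divisible by 3.  Codons whose expansion includes
    a stop are flagged (``on_stop``: "warn" drops the stop translations with
    a warning, "error" raises); the remaining translations stay available.
    """
    dna = "".join(text.split()).upper()
    if len(dna) % 3 != 0:
        raise TemplateError(f"DNA template length {len(dna)} is not divisible by 3")
    positions: list[tuple[str, ...]] = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        residues, has_stop = _codon_options(codon)
        if has_stop:
            if on_stop == "error":
                raise TemplateError(f"codon {codon!r} (position {i // 3 + 1}) encodes a stop")
            warnings.warn(
                f"codon {codon!r} (position {i // 3 + 1}) encodes a stop; "
                "stop translations dropped",
                UserWarning,
                stacklevel=2,
            )
        if not residues:
            raise TemplateError(f"codon {codon!r} encodes only stops")
        positions.append(residues)
    return LibraryTemplate(
        positions=tuple(positions),
        mode="dna",
        start_letter=start_letter,
        cap_prefix=cap_prefix,
        cap_suffix=cap_suffix,
    )


def expand_degenerate_dna(
    text: str,
    *,
    start_letter: str = "g",
    cap_prefix: str = "",
    cap_suffix: str = "",
    on_stop: str = "warn",
) -> Iterator[str]:
    """Expand a degenerate DNA template and stream unique peptide sequences.

    Synonymous codons collapse: deduplication happens at the protein level,
    per position (each codon contributes a residue-option set) — a library
    is a set of peptides, not of genes.
    """
    template = parse_dna_template(
        text,
        start_letter=start_letter,
        cap_prefix=cap_prefix,
        cap_suffix=cap_suffix,
        on_stop=on_stop,
    )
    for combo in itertools.product(*template.positions):
        yield cap_prefix + "".join(combo) + cap_suffix
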