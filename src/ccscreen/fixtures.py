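"""Built-in reference inputs: the eight-peptide set and its parent template.

The package ships, as executable fixtures, the 27-position degenerate
template of the four-heptad Glu/Lys-Asn/Ile design family and the reference
set of eight capped 32-residue peptides selected from it — four designed
heterodimers (1-2, 3-4, 5-6, 7-8) that are mutually orthogonal: every
desired pair makes two Asn-Asn and two Ile-Ile core contacts and eight
attractive Glu-Lys flanking contacts, while all 32 off-target pairings are
penalised in the core, the flanks, or both.

Chains are registered g-first/e-last so that all eight e/g electrostatic
contacts are made and none dangles at a terminus; the ``AS`` and ``GAP``
flanks are helix caps excluded from scoring, and the single Tyr at an f
position aids concentration determination.
"""

from __future__ import annotations

from .heptad import RegisteredPeptide, assign_register
from .libgen import CompositionConstraint, LibraryTemplate, parse_template

__all__ = [
    "TEMPLATE_TEXT",
    "TEMPLATE_SYMBOLS",
    "CAP_PREFIX",
    "CAP_SUFFIX",
    "OCTET_SEQUENCES",
    "library_template",
    "core_constraint",
    "reference_octet",
]

#: 27-position core template: h = Asn/Ile at the four a positions,
#: p = Glu/Lys at the four g and four e positions; all else fixed.
TEMPLATE_TEXT = "phAALpAphAALpYphAALpAphAALp"
TEMPLATE_SYMBOLS = {"h": ("I", "N"), "p": ("E", "K")}

#: Helix-capping flanks added to every synthesised member (register caps).
CAP_PREFIX = "AS"
CAP_SUFFIX = "GAP"

#: The eight selected 32-residue peptides (caps included).
OCTET_SEQUENCES = {
    "pep1": "ASENAALEAKNAALKYKIAALKAEIAALEGAP",
    "pep2": "ASKNAALKAENAALEYEIAALEAKIAALKGAP",
    "pep3": "ASEIAALEAEIAALEYENAALEAENAALEGAP",
    "pep4": "ASKIAALKAKIAALKYKNAALKAKNAALKGAP",
    "pep5": "ASKNAALKAEIAALEYKIAALKAENAALEGAP",
    "pep6": "ASENAALEAKIAALKYEIAALEAKNAALKGAP",
    "pep7": "ASKIAALKAKNAALKYENAALEAEIAALEGAP",
    "pep8": "ASEIAALEAENAALEYKNAALKAKIAALKGAP",
}

#: The four designed heterodimers within the octet.
DESIRED_PAIRS = (("pep1", "pep2"), ("pep3", "pep4"), ("pep5", "pep6"), ("pep7", "pep8"))


def library_template() -> LibraryTemplate:
    """The capped, g-registered 27-position template (product size 4096)."""
    return parse_template(
        TEMPLATE_TEXT,
        TEMPLATE_SYMBOLS,
        start_letter="g",
        cap_prefix=CAP_PREFIX,
        cap_suffix=CAP_SUFFIX,
    )


def core_constraint() -> CompositionConstraint:
    """Exactly two Asn and two Ile at the four a positions (4096 -> 1536)."""
    return CompositionConstraint(register_letter="a", residue_counts={"N": 2, "I": 2})


def reference_octet() -> list[RegisteredPeptide]:
    """The eight reference peptides with g-start registers and 2/3 caps."""
    return [
        assign_register(seq, "g", len(CAP_PREFIX), len(CAP_SUFFIX), id=pid)
        for pid, seq in OCTET_SEQUENCES.items()
    ]
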