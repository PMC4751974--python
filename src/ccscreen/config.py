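"""Run configuration: YAML serialisation of tables, model and criteria.

One YAML file drives the whole pipeline; CLI flags override file values,
which override the built-in defaults.  Sections:

``score_tables``
    ``core`` / ``electro`` mappings of two-letter residue pairs to kcal/mol
    (e.g. ``II: -9.2``) and a ``default_missing`` policy.
``helicity``
    either the name of a shipped scale (``pace-scholtz``) or an explicit
    20-residue mapping.
``tm_model``
    ``name`` plus ``coefficients`` (w_hp, w_cs, w_es, intercept).
``criteria``
    the screening thresholds (see ScreenCriteria).
``template``
    text, wildcard symbol table, start letter, caps, optional composition
    ``constraint`` string such as ``"a:N=2,I=2"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .libgen import CompositionConstraint, LibraryTemplate, parse_template
from .scoring import (
    DEFAULT_PAIR_SCORES,
    PACE_SCHOLTZ,
    HelicityTable,
    PairScoreTable,
    TmModel,
    default_tm_model,
)
from .screen import ScreenCriteria

__all__ = [
    "RunConfig",
    "parse_constraint",
    "load_config",
    "default_config_dict",
    "save_config",
]

_HELICITY_SCALES = {"pace-scholtz": PACE_SCHOLTZ}


def parse_constraint(text: str) -> CompositionConstraint:
    """Parse ``"a:N=2,I=2"`` into an exact-count composition constraint."""
    try:
        letter, body = text.split(":", 1)
        counts = {}
        for item in body.split(","):
            res, n = item.split("=")
            counts[res.strip()] = int(n)
    except ValueError as exc:
        raise ValueError(f"malformed constraint {text!r} (expected 'a:N=2,I=2')") from exc
    return CompositionConstraint(register_letter=letter.strip(), residue_counts=counts)


def _pair_map(raw: Mapping[str, float]) -> dict[tuple[str, str], float]:
    out = {}
    for key, v in raw.items():
        if len(key) != 2:
            raise ValueError(f"score-table key {key!r} is not a two-letter residue pair")
        out[(key[0], key[1])] = float(v)
    return out


@dataclass
class RunConfig:
    """Everything a pipeline run needs, resolved into live objects."""

    model: TmModel
    criteria: ScreenCriteria
    template: LibraryTemplate | None = None
    constraint: CompositionConstraint | None = None
    library_path: str | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        raw = dict(raw or {})
        st = raw.get("score_tables") or {}
        if st:
            scores = PairScoreTable(
                core=_pair_map(st.get("core") or {}),
                electro=_pair_map(st.get("electro") or {}),
                default_missing=st.get("default_missing", "error"),
            )
        else:
            scores = DEFAULT_PAIR_SCORES

        hel_raw = (raw.get("helicity") or {}).get("table", "pace-scholtz")
        if isinstance(hel_raw, str):
            try:
                helicity = HelicityTable(_HELICITY_SCALES[hel_raw], name=hel_raw)
            except KeyError:
                raise ValueError(f"unknown helicity scale {hel_raw!r}") from None
        else:
            helicity = HelicityTable({k: float(v) for k, v in hel_raw.items()})

        tm_raw = raw.get("tm_model") or {}
        coeff = tm_raw.get("coefficients")
        if coeff is None:
            base = default_tm_model()
            model = TmModel(
                base.w_hp, base.w_cs, base.w_es, base.intercept,
                helicity=helicity, scores=scores, name=base.name,
            )
        else:
            try:
                model = TmModel(
                    w_hp=float(coeff["w_hp"]),
                    w_cs=float(coeff["w_cs"]),
                    w_es=float(coeff["w_es"]),
                    intercept=float(coeff["intercept"]),
                    helicity=helicity,
                    scores=scores,
                    name=tm_raw.get("name", "custom"),
                )
            except KeyError as exc:
                raise ValueError(f"tm_model.coefficients missing {exc}") from None

        criteria = ScreenCriteria(**(raw.get("criteria") or {}))

        template = None
        constraint = None
        tpl = raw.get("template")
        if tpl:
            template = parse_template(
                tpl["text"],
                {s: tuple(opts) for s, opts in (tpl.get("symbols") or {}).items()},
                start_letter=tpl.get("start_letter", "g"),
                cap_prefix=tpl.get("cap_prefix", ""),
                cap_suffix=tpl.get("cap_suffix", ""),
            )
            if tpl.get("constraint"):
                constraint = parse_constraint(tpl["constraint"])

        return cls(
            model=model,
            criteria=criteria,
            template=template,
            constraint=constraint,
            library_path=raw.get("library"),
            seed=int(raw.get("seed", 0)),
        )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.from_dict(raw or {})


def default_config_dict() -> dict[str, Any]:
    """The built-in defaults as a plain serialisable mapping."""
    base = default_tm_model()
    return {
        "score_tables": {
            "core": {"II": -9.2, "NN": -2.4, "NI": -0.5},
            "electro": {"EK": -1.2, "EE": 0.4, "KK": -0.3},
            "default_missing": "error",
        },
        "helicity": {"table": "pace-scholtz"},
        "tm_model": {
            "name": base.name,
            "coefficients": {
                "w_hp": base.w_hp,
                "w_cs": base.w_cs,
                "w_es": base.w_es,
                "intercept": base.intercept,
            },
        },
        "criteria": {
            "max_homodimer_tm": 10.0,
            "min_desired_tm": 70.0,
            "max_offtarget_tm_pairs": 20.0,
            "min_delta_tm_pairs": 50.0,
            "max_offtarget_tm_quads": 30.0,
            "min_delta_tm_quads": 40.0,
            "antiparallel_filter": False,
        },
        "seed": 0,
    }


def save_config(raw: Mapping[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(raw), fh, sort_keys=True)
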