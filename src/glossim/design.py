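"""Factorial stimulus designs and the specular-parameter → reflectance mapping.

Glossy-object stimulus sets in this line of work are factorial grids over a
small number of surface-reflectance parameters (base colour, specular
strength, specular tint, microroughness, anisotropy), with *nesting rules*
that make some levels conditional on others — e.g. anisotropy only applies
to surfaces with non-zero roughness.  :class:`DesignSpec` expresses such a
grid declaratively and :func:`enumerate_design` expands it into the full,
duplicate-free list of :class:`StimulusParams`.

Two designs are built in:

``exp1``
    270-stimulus free-naming grid: one shape (dragon) in one light field
    (kitchen), 6 base colours × 3 specular levels × roughness/anisotropy
    nesting.
``exp2``
    924-stimulus forced-choice / gloss-rating grid: 2 shapes × 2 light
    fields, with a fourth (40 % reflectance) specular level restricted to
    the four darkest base colours.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Sequence

__all__ = [
    "StimulusParams",
    "ParameterDef",
    "DesignSpec",
    "enumerate_design",
    "specular_to_reflectance",
    "builtin_design",
    "BUILTIN_DESIGNS",
]

#: Facing specular reflectance (percent) corresponding to parameter value 1.0.
#: The normalized specular parameter maps linearly onto the 0–8 % incident
#: range covering common dielectrics; values above 1 extrapolate linearly
#: (5 → 40 %, metal-like).
REFLECTANCE_PERCENT_AT_UNIT_LEVEL = 8.0


def specular_to_reflectance(level: float) -> float:
    """Map a normalized specular-strength parameter to facing reflectance (%).

    The mapping is linear with parameter 1.0 at the top of the 0–8 % range:
    ``specular_to_reflectance(0.1) == 0.8`` and
    ``specular_to_reflectance(5) == 40.0``.

    Parameters
    ----------
    level
        Non-negative specular parameter.

    Returns
    -------
    float
        Facing specular reflectance in percent.
    """
    level = float(level)
    if level < 0:
        raise ValueError(f"specular level must be >= 0, got {level}")
    return level * REFLECTANCE_PERCENT_AT_UNIT_LEVEL


@dataclass(frozen=True)
class StimulusParams:
    """One cell of the factorial rendering design."""

    shape: str = "dragon"
    light_field: str = "kitchen"
    base_saturation: str = "greyscale"
    base_value: str = "medium"
    base_rgb: tuple[float, float, float] = (0.1, 0.1, 0.1)
    specular_level: float = 0.3
    specular_tint: float = 0.0
    roughness: float = 0.0
    anisotropic: float = 0.0
    aniso_rotation: float = 0.0

    def __post_init__(self) -> None:
        if self.specular_level < 0:
            raise ValueError(f"specular_level must be >= 0, got {self.specular_level}")
        if self.roughness < 0:
            raise ValueError(f"roughness must be >= 0, got {self.roughness}")
        if self.anisotropic > 0 and self.roughness == 0:
            raise ValueError("anisotropic > 0 requires roughness > 0")
        if self.aniso_rotation != 0 and self.anisotropic == 0:
            raise ValueError("aniso_rotation != 0 requires anisotropic > 0")
        if any(c < 0 for c in self.base_rgb):
            raise ValueError(f"base_rgb must be non-negative, got {self.base_rgb}")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["base_rgb"] = list(self.base_rgb)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StimulusParams":
        d = dict(d)
        d["base_rgb"] = tuple(d["base_rgb"])
        return cls(**d)


@dataclass(frozen=True)
class ParameterDef:
    """Levels of one design parameter, possibly conditional on earlier ones.

    ``clauses`` is an ordered list of ``(when, levels)`` pairs; the first
    clause whose ``when`` dict (parameter name → allowed values) matches the
    partial assignment supplies the levels.  ``when`` may only reference
    parameters declared earlier.  A final unconditional clause uses
    ``when={}``.
    """

    name: str
    clauses: tuple[tuple[tuple[tuple[str, tuple], ...], tuple], ...]

    @classmethod
    def fixed(cls, name: str, levels: Sequence) -> "ParameterDef":
        return cls(name, (((), tuple(levels)),))

    @classmethod
    def conditional(cls, name: str, clauses: Sequence[tuple[dict, Sequence]]) -> "ParameterDef":
        packed = []
        for when, levels in clauses:
            packed.append((tuple((k, tuple(v)) for k, v in when.items()), tuple(levels)))
        return cls(name, tuple(packed))

    def levels_for(self, assignment: dict[str, Any]) -> tuple:
        for when, levels in self.clauses:
            if all(assignment.get(k) in vals for k, vals in when):
                return levels
        raise ValueError(
            f"no clause of parameter {self.name!r} matches assignment {assignment!r}"
        )


@dataclass(frozen=True)
class DesignSpec:
    """A declarative factorial design with nesting rules.

    Parameters are expanded in declaration order (the canonical enumeration
    order), so conditional clauses may only reference earlier parameters.
    ``base_rgb_table`` maps ``(base_saturation, base_value)`` to the RGB
    triplet of the diffuse base colour.
    """

    name: str
    parameters: tuple[ParameterDef, ...]
    base_rgb_table: tuple[tuple[tuple[str, str], tuple[float, float, float]], ...] = ()

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.parameters:
            for when, _levels in p.clauses:
                for ref, _vals in when:
                    if ref not in seen:
                        raise ValueError(
                            f"parameter {p.name!r} conditions on undeclared or later "
                            f"parameter {ref!r}"
                        )
            seen.add(p.name)

    def rgb_for(self, saturation: str, value: str) -> tuple[float, float, float]:
        for key, rgb in self.base_rgb_table:
            if key == (saturation, value):
                return rgb
        raise KeyError(f"no base colour for ({saturation!r}, {value!r})")


def enumerate_design(spec: DesignSpec) -> list[StimulusParams]:
    """Expand a :class:`DesignSpec` into the full list of stimulus parameters.

    Enumeration is depth-first over the parameters in declaration order with
    levels in their declared order, which makes the output order canonical
    and stable.  The expansion is duplicate-free by construction (each cell
    is a distinct assignment).
    """
    cells: list[dict[str, Any]] = [{}]
    for p in spec.parameters:
        nxt = []
        for cell in cells:
            for lv in p.levels_for(cell):
                c = dict(cell)
                c[p.name] = lv
                nxt.append(c)
        cells = nxt
    out = []
    for cell in cells:
        if spec.base_rgb_table:
            cell["base_rgb"] = tuple(spec.rgb_for(cell["base_saturation"], cell["base_value"]))
        out.append(StimulusParams(**cell))
    if len(set(out)) != len(out):
        raise ValueError("design enumeration produced duplicates")
    return out


def _colour_table(grey_values: dict[str, float],
                  sat_values: dict[str, tuple[float, float, float]]):
    table = []
    for value, g in grey_values.items():
        table.append((("greyscale", value), (g, g, g)))
    for value, rgb in sat_values.items():
        table.append((("saturated", value), rgb))
    return tuple(table)


def _roughness_block(roughness_levels: Sequence[float]) -> list[ParameterDef]:
    rough_nonzero = tuple(r for r in roughness_levels if r > 0)
    return [
        ParameterDef.fixed("roughness", roughness_levels),
        ParameterDef.conditional("anisotropic", [
            ({"roughness": rough_nonzero}, (0.0, 0.9)),
            ({}, (0.0,)),
        ]),
        ParameterDef.conditional("aniso_rotation", [
            ({"anisotropic": (0.9,)}, (0.0, 0.25)),
            ({}, (0.0,)),
        ]),
    ]


def _exp1_spec() -> DesignSpec:
    # Free-naming grid: dragon/kitchen only; 3 specular levels everywhere;
    # 4 roughness levels; tint only for saturated base colours.
    return DesignSpec(
        name="exp1",
        parameters=tuple([
            ParameterDef.fixed("shape", ("dragon",)),
            ParameterDef.fixed("light_field", ("kitchen",)),
            ParameterDef.fixed("base_saturation", ("greyscale", "saturated")),
            ParameterDef.fixed("base_value", ("dark", "medium", "light")),
            ParameterDef.fixed("specular_level", (0.1, 0.3, 1.0)),
            ParameterDef.conditional("specular_tint", [
                ({"base_saturation": ("saturated",)}, (0.0, 1.0)),
                ({}, (0.0,)),
            ]),
            *_roughness_block((0.0, 0.1, 0.3, 0.6)),
        ]),
        base_rgb_table=_colour_table(
            {"dark": 0.01, "medium": 0.1, "light": 0.3},
            {"dark": (0.01, 0.007, 0.001),
             "medium": (0.1, 0.074, 0.01),
             "light": (0.3, 0.221, 0.03)},
        ),
    )


def _exp2_spec() -> DesignSpec:
    # Forced-choice / gloss-rating grid: 2 shapes × 2 light fields; the 40 %
    # specular level (parameter 5) applies only to the darkest four base
    # colours, i.e. the dark and medium values of both saturations.
    return DesignSpec(
        name="exp2",
        parameters=tuple([
            ParameterDef.fixed("shape", ("dragon", "bunny")),
            ParameterDef.fixed("light_field", ("kitchen", "campus")),
            ParameterDef.fixed("base_saturation", ("greyscale", "saturated")),
            ParameterDef.fixed("base_value", ("dark", "medium", "light")),
            ParameterDef.conditional("specular_level", [
                ({"base_value": ("dark", "medium")}, (0.1, 0.3, 1.0, 5.0)),
                ({}, (0.1, 0.3, 1.0)),
            ]),
            ParameterDef.conditional("specular_tint", [
                ({"base_saturation": ("saturated",)}, (0.0, 1.0)),
                ({}, (0.0,)),
            ]),
            *_roughness_block((0.0, 0.3, 0.6)),
        ]),
        base_rgb_table=_colour_table(
            {"dark": 0.01, "medium": 0.03, "light": 0.3},
            {"dark": (0.01, 0.007, 0.001),
             "medium": (0.03, 0.022, 0.003),
             "light": (0.3, 0.221, 0.03)},
        ),
    )


BUILTIN_DESIGNS = {"exp1": _exp1_spec, "exp2": _exp2_spec}


def builtin_design(name: str) -> DesignSpec:
    """Return a built-in design (``exp1`` or ``exp2``)."""
    try:
        return BUILTIN_DESIGNS[name]()
    except KeyError:
        raise KeyError(
            f"unknown design {name!r}; available: {sorted(BUILTIN_DESIGNS)}"
        ) from None
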