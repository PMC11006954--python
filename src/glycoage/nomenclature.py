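"""Oxford-notation glycan names and their monosaccharide compositions.

The Oxford (shorthand) nomenclature encodes an N-glycan's composition in a
compact string read left to right:

``F``      core fucose attached to the reducing-end GlcNAc (0 or 1);
``A<n>``   number of antennae (GlcNAc branches) on the trimannosyl core;
``B``      bisecting GlcNAc (0 or 1);
``G<n>``   number of terminal galactoses (at most one per antenna);
``S<n>``   number of sialic acids capping galactoses (at most one per
           galactose).

An optional branch tag such as ``[3]`` or ``[6]`` directly before ``G``
marks which core-mannose arm carries the galactose on mono-galactosylated
isomers (e.g. ``FA2[3]G1`` vs ``FA2[6]G1``).  Branch tags distinguish
chromatographically separable isomers but not compositions: both parse to
the same monosaccharide counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["GlycanComposition", "GlycanNameError", "parse_oxford_name", "compose_name"]


class GlycanNameError(ValueError):
    """Raised when a glycan name does not follow the Oxford grammar."""


_NAME_RE = re.compile(
    r"""^
    (?P<fuc>F)?
    A(?P<ant>\d+)
    (?P<bis>B)?
    (?:(?P<tag>\[\d\])?G(?P<gal>\d+))?
    (?:S(?P<sia>\d+))?
    $""",
    re.VERBOSE,
)


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide content decoded from an Oxford-notation name."""

    name: str
    core_fucose: int
    antennae: int
    bisecting: int
    galactoses: int
    sialic_acids: int
    branch_tag: str | None = None

    def __post_init__(self) -> None:
        if self.core_fucose not in (0, 1):
            raise GlycanNameError(f"{self.name!r}: core fucose must be 0 or 1")
        if self.bisecting not in (0, 1):
            raise GlycanNameError(f"{self.name!r}: bisecting GlcNAc must be 0 or 1")
        if not (0 <= self.galactoses <= self.antennae):
            raise GlycanNameError(
                f"{self.name!r}: galactose count {self.galactoses} exceeds "
                f"antennae count {self.antennae}"
            )
        if not (0 <= self.sialic_acids <= self.galactoses):
            raise GlycanNameError(
                f"{self.name!r}: sialic acid count {self.sialic_acids} exceeds "
                f"galactose count {self.galactoses}"
            )

    @property
    def canonical_name(self) -> str:
        """The composition re-encoded as an Oxford name, branch tags dropped."""
        return compose_name(
            core_fucose=self.core_fucose,
            antennae=self.antennae,
            bisecting=self.bisecting,
            galactoses=self.galactoses,
            sialic_acids=self.sialic_acids,
        )


def parse_oxford_name(name: str) -> GlycanComposition:
    """Parse an Oxford-notation glycan name into its composition.

    Parameters
    ----------
    name
        Glycan name such as ``"FA2BG2"``, ``"A2G2S2"`` or ``"FA2[3]G1"``.

    Returns
    -------
    GlycanComposition
        Counts of core fucose, antennae, bisecting GlcNAc, galactoses and
        sialic acids, plus the branch tag if one was present.

    Raises
    ------
    GlycanNameError
        If the name does not match the grammar or violates a compositional
        constraint (e.g. more galactoses than antennae).
    """
    if not isinstance(name, str) or not name:
        raise GlycanNameError(f"not a glycan name: {name!r}")
    m = _NAME_RE.match(name.strip())
    if m is None:
        raise GlycanNameError(
            f"{name!r} does not follow the Oxford grammar "
            "F? A<n> B? [<arm>]? G<n>? S<n>?"
        )
    return GlycanComposition(
        name=name.strip(),
        core_fucose=1 if m.group("fuc") else 0,
        antennae=int(m.group("ant")),
        bisecting=1 if m.group("bis") else 0,
        galactoses=int(m.group("gal") or 0),
        sialic_acids=int(m.group("sia") or 0),
        branch_tag=m.group("tag"),
    )


def compose_name(
    *,
    core_fucose: int,
    antennae: int,
    bisecting: int,
    galactoses: int,
    sialic_acids: int,
) -> str:
    """Encode a composition as a canonical Oxford name (no branch tags)."""
    parts = []
    if core_fucose:
        parts.append("F")
    parts.append(f"A{antennae}")
    if bisecting:
        parts.append("B")
    if galactoses:
        parts.append(f"G{galactoses}")
    if sialic_acids:
        parts.append(f"S{sialic_acids}")
    return "".join(parts)
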