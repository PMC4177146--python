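"""Static ball-and-stick rendering to SVG with painter's-algorithm depth
sorting.

The projection is orthographic: x, y map to the canvas (y flipped, screen
convention), z is depth with the viewer looking along +z, so the atom with
the smallest z is backmost and drawn first.  Each atom is drawn as a filled
circle (radius = sphere_scale × covalent radius, radial-gradient shaded),
followed by one line per bond to every bonded atom in front of it; the line
starts where the bond pierces the back atom's sphere in 3D and ends at the
front atom's projected center.  Spheres are assumed not to overlap — no
occlusion handling beyond the painter's order.

For molecules with more than ``gradient_cutoff`` atoms (default 250) the
radial gradients are dropped and circles use flat element-color fills,
since gradient shading is the expensive part of drawing large structures.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np

from .elements import default_table
from .errors import EmptyMoleculeError
from .molecule import Molecule

__all__ = ["Scene", "depth_sort", "render"]

_HIGHLIGHT_COLOR = "#FFFFA0"  # light yellow


@dataclass(frozen=True)
class Scene:
    """Projection and styling parameters for a rendering."""

    width: int = 400
    height: int = 400
    scale: float = 60.0  # px per Å
    sphere_scale: float = 0.5  # drawn sphere radius = sphere_scale × covalent radius
    gradient_cutoff: int = 250  # flat fills above this atom count
    label_atoms: bool = False
    highlight_set: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0 or self.scale <= 0:
            raise ValueError("width, height and scale must be positive")
        if self.gradient_cutoff <= 0:
            raise ValueError("gradient_cutoff must be positive")


def depth_sort(molecule: Molecule) -> list[int]:
    """Atom indices ordered back-to-front (ascending z), stable on ties."""
    zs = [a.position[2] for a in molecule.atoms]
    return sorted(range(len(zs)), key=lambda i: zs[i])


def _hex(color: tuple[int, int, int]) -> str:
    return "#{:02X}{:02X}{:02X}".format(*color)


def _lighter(color, f=0.6):
    return tuple(int(c + (255 - c) * f) for c in color)


def _darker(color, f=0.45):
    return tuple(int(c * (1 - f)) for c in color)


def render(molecule: Molecule, scene: Scene = Scene()) -> str:
    """Render to an SVG document string."""
    if len(molecule) == 0:
        raise EmptyMoleculeError("nothing to render")
    table = default_table()
    coords = molecule.coords
    center = coords.mean(axis=0)

    def project(p: np.ndarray) -> tuple[float, float]:
        x = scene.width / 2.0 + scene.scale * (p[0] - center[0])
        y = scene.height / 2.0 - scene.scale * (p[1] - center[1])
        return x, y

    use_gradients = len(molecule) <= scene.gradient_cutoff
    svg = ET.Element(
        "svg",
        xmlns="http://www.w3.org/2000/svg",
        width=str(scene.width),
        height=str(scene.height),
        viewBox=f"0 0 {scene.width} {scene.height}",
    )

    order = depth_sort(molecule)
    rank = {atom: pos for pos, atom in enumerate(order)}
    symbols = molecule.symbols

    if use_gradients:
        defs = ET.SubElement(svg, "defs")
        for sym in sorted(set(symbols)):
            color = table.lookup(sym).color
            grad = ET.SubElement(
                defs, "radialGradient", id=f"grad-{sym}", cx="35%", cy="35%", r="80%"
            )
            # off-center highlight fading to a darkened rim
            for offset, col in (("0%", _lighter(color)), ("45%", color), ("100%", _darker(color))):
                ET.SubElement(grad, "stop", offset=offset, attrib={"stop-color": _hex(col)})

    for idx in order:
        rec = table.lookup(symbols[idx])
        pos = molecule.atoms[idx].position
        cx, cy = project(pos)
        r_draw_3d = scene.sphere_scale * rec.covalent_radius  # Å
        r_px = r_draw_3d * scene.scale

        if idx in scene.highlight_set:
            ET.SubElement(
                svg, "circle",
                cx=f"{cx:.2f}", cy=f"{cy:.2f}", r=f"{r_px * 1.35:.2f}",
                fill=_HIGHLIGHT_COLOR,
                attrib={"class": "highlight"},
            )
        fill = f"url(#grad-{rec.symbol})" if use_gradients else _hex(rec.color)
        ET.SubElement(
            svg, "circle",
            cx=f"{cx:.2f}", cy=f"{cy:.2f}", r=f"{r_px:.2f}", fill=fill,
            attrib={"class": "atom", "data-atom": str(idx), "data-z": f"{pos[2]:.6f}"},
        )
        # bonds owned by the back atom: one line to each bonded atom in front
        for nbr in molecule.neighbors(idx):
            if rank[nbr] <= rank[idx]:
                continue
            npos = molecule.atoms[nbr].position
            d = npos - pos
            norm = np.linalg.norm(d)
            # start on the sphere surface along the bond (3D), clamped for
            # bonds shorter than the drawn radius
            start3d = pos + (min(r_draw_3d, norm) / norm) * d if norm > 0 else pos
            x1, y1 = project(start3d)
            x2, y2 = project(npos)
            ET.SubElement(
                svg, "line",
                x1=f"{x1:.2f}", y1=f"{y1:.2f}", x2=f"{x2:.2f}", y2=f"{y2:.2f}",
                stroke="#303030",
                attrib={"stroke-width": "2", "class": "bond",
                        "data-bond": f"{min(idx, nbr)}-{max(idx, nbr)}"},
            )
        if scene.label_atoms:
            label = ET.SubElement(
                svg, "text",
                x=f"{cx:.2f}", y=f"{cy:.2f}",
                attrib={"text-anchor": "middle", "dominant-baseline": "middle",
                        "font-size": "12", "class": "label"},
            )
            label.text = f"{rec.symbol}{idx + 1}"

    return ET.tostring(svg, encoding="unicode")
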