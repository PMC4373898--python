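"""Ideal α-helix projection and cavity annotation for motif matches.

A signal anchor is modelled as a strict α-helix: 100° of rotation per
residue (3.6 residues per turn), so residue i sits at azimuth
((i − 1) × 100) mod 360. The two small-residue patches of a CCM match are
projected onto the helix surface as two cavities; the annotation reports
each cavity's member azimuths, circular-mean centroid and the angular
separation between the centroids. This is display geometry, not molecular
modelling — no 3D coordinates or solvent-accessible surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ValidationError
from .motif import MotifMatch

DEGREES_PER_RESIDUE = 100.0  # ideal alpha helix, 3.6 residues/turn


@dataclass(frozen=True)
class HelixProjection:
    """Azimuth (degrees in [0, 360)) per residue of an ideal helix."""

    azimuths: tuple[float, ...]
    degrees_per_residue: float = DEGREES_PER_RESIDUE

    def azimuth(self, position: int) -> float:
        """Azimuth of a 1-based residue position."""
        if not 1 <= position <= len(self.azimuths):
            raise ValidationError(f"position {position} outside projection")
        return self.azimuths[position - 1]

    def __len__(self) -> int:
        return len(self.azimuths)


def project_helix(sequence: str, degrees_per_residue: float = DEGREES_PER_RESIDUE) -> HelixProjection:
    if not sequence:
        raise ValidationError("empty sequence")
    az = tuple(float((i * degrees_per_residue) % 360.0) for i in range(len(sequence)))
    return HelixProjection(azimuths=az, degrees_per_residue=degrees_per_residue)


def circular_mean_deg(angles: np.ndarray | list[float]) -> float:
    """Circular mean of angles in degrees, result in [0, 360)."""
    rad = np.deg2rad(np.asarray(angles, dtype=float))
    mean = np.rad2deg(np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad))))
    wrapped = float(mean % 360.0)
    return 0.0 if wrapped >= 360.0 - 1e-12 else wrapped


def angular_separation_deg(a: float, b: float) -> float:
    """Smallest angle between two azimuths, in [0, 180]."""
    d = abs(a - b) % 360.0
    return float(min(d, 360.0 - d))


@dataclass(frozen=True)
class CavityAnnotation:
    """The two small-residue surface cavities of one motif match."""

    cavity1_positions: tuple[int, ...]
    cavity2_positions: tuple[int, ...]
    cavity1_azimuths: tuple[float, ...]
    cavity2_azimuths: tuple[float, ...]
    cavity1_centroid: float
    cavity2_centroid: float
    centroid_separation: float


def annotate_cavities(
    sequence: str, match: MotifMatch, projection: HelixProjection
) -> CavityAnnotation:
    """Project a match's two small patches onto the helix surface.

    A pure function of the match positions and the projection; the
    residue identities themselves are not consulted.
    """
    if match.end > len(projection) or match.end > len(sequence):
        raise ValidationError(
            f"match ending at {match.end} out of bounds for length {len(sequence)}"
        )
    c1 = tuple(range(match.patch1_span[0], match.patch1_span[1] + 1))
    c2 = tuple(range(match.patch2_span[0], match.patch2_span[1] + 1))
    az1 = tuple(projection.azimuth(p) for p in c1)
    az2 = tuple(projection.azimuth(p) for p in c2)
    cen1 = circular_mean_deg(list(az1))
    cen2 = circular_mean_deg(list(az2))
    return CavityAnnotation(
        cavity1_positions=c1,
        cavity2_positions=c2,
        cavity1_azimuths=az1,
        cavity2_azimuths=az2,
        cavity1_centroid=cen1,
        cavity2_centroid=cen2,
        centroid_separation=angular_separation_deg(cen1, cen2),
    )


def helical_wheel_svg(
    sequence: str,
    projection: HelixProjection | None = None,
    annotation: CavityAnnotation | None = None,
    radius: float = 120.0,
) -> str:
    """Render a simple helical-wheel SVG (cavity residues highlighted)."""
    if projection is None:
        projection = project_helix(sequence)
    cavity = set()
    if annotation is not None:
        cavity = set(annotation.cavity1_positions) | set(annotation.cavity2_positions)
    size = 2 * (radius + 30)
    cx = cy = size / 2
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size:.0f}" height="{size:.0f}">',
        f'<circle cx="{cx}" cy="{cy}" r="{radius}" fill="none" stroke="#ccc"/>',
    ]
    for i, residue in enumerate(sequence, start=1):
        theta = np.deg2rad(projection.azimuth(i) - 90.0)
        x = cx + radius * np.cos(theta)
        y = cy + radius * np.sin(theta)
        color = "#2a9d2a" if i in cavity else "#333"
        parts.append(
            f'<circle cx="{x:.1f}" cy="{y:.1f}" r="11" fill="white" stroke="{color}"/>'
            f'<text x="{x:.1f}" y="{y + 4:.1f}" font-size="11" text-anchor="middle" '
            f'fill="{color}">{residue}{i}</text>'
        )
    parts.append("</svg>")
    return "\n".join(parts)
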