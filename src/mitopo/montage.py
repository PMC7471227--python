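"""Electrode geometry for the 22-channel motor-imagery montage.

The montage is an idealised unit-sphere layout of the 22 electrodes used by
the BCI Competition IV 2a cap (10-20/10-10 labels, channel index 1..22 in the
order below).  Positions are built from two rotations of the vertex:

* rotate by ``alpha`` about the ear-to-ear (x) axis towards the nose (+y),
* then by ``beta`` about the nose (y) axis towards the left ear (-x),

with 18 degrees per 10% arc step of the 10-20 system.  The 2D view is an
azimuthal equidistant projection looking down at the head top: nose up (+y),
left ear at -x, vertex (Cz) at the origin, the equator on the unit circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Electrode",
    "Montage",
    "standard_montage_22",
    "project_azimuthal",
    "sensorimotor_subset",
    "save_montage",
    "load_montage",
    "SENSORIMOTOR_LABELS",
]

# label -> (alpha: degrees towards nose, beta: degrees towards left ear).
# Order defines the channel index c = 1..22 of the Dataset-2a montage.
_ANGLES_22: tuple[tuple[str, float, float], ...] = (
    ("Fz", 36.0, 0.0),
    ("FC3", 18.0, 36.0),
    ("FC1", 18.0, 18.0),
    ("FCz", 18.0, 0.0),
    ("FC2", 18.0, -18.0),
    ("FC4", 18.0, -36.0),
    ("C5", 0.0, 54.0),
    ("C3", 0.0, 36.0),
    ("C1", 0.0, 18.0),
    ("Cz", 0.0, 0.0),
    ("C2", 0.0, -18.0),
    ("C4", 0.0, -36.0),
    ("C6", 0.0, -54.0),
    ("CP3", -18.0, 36.0),
    ("CP1", -18.0, 18.0),
    ("CPz", -18.0, 0.0),
    ("CP2", -18.0, -18.0),
    ("CP4", -18.0, -36.0),
    ("P1", -36.0, 18.0),
    ("Pz", -36.0, 0.0),
    ("P2", -36.0, -18.0),
    ("POz", -54.0, 0.0),
)

#: The 10 sensorimotor electrodes used by the prior dropping strategy
#: (C3, channels 9-11, C4, channels 14-18), in montage order.
SENSORIMOTOR_LABELS: tuple[str, ...] = (
    "C3", "C1", "Cz", "C2", "C4", "CP3", "CP1", "CPz", "CP2", "CP4",
)


@dataclass(frozen=True)
class Electrode:
    """A single electrode: label, unit-sphere position, optional disk position."""

    label: str
    position3d: np.ndarray
    position2d: np.ndarray | None = None

    def __post_init__(self) -> None:
        p3 = np.asarray(self.position3d, dtype=float)
        object.__setattr__(self, "position3d", p3)
        if abs(np.linalg.norm(p3) - 1.0) > 1e-9:
            raise ValueError(f"electrode {self.label!r}: |position3d| must be 1")
        if self.position2d is not None:
            p2 = np.asarray(self.position2d, dtype=float)
            object.__setattr__(self, "position2d", p2)
            if np.hypot(*p2) > 1.0 + 1e-12:
                raise ValueError(f"electrode {self.label!r}: position2d outside unit disk")


@dataclass(frozen=True)
class Montage:
    """An ordered set of electrodes; the order fixes the channel index c."""

    electrodes: tuple[Electrode, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "electrodes", tuple(self.electrodes))
        labels = [e.label for e in self.electrodes]
        if len(set(labels)) != len(labels):
            raise ValueError("montage labels must be unique")

    def __len__(self) -> int:
        return len(self.electrodes)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.electrodes]

    @property
    def positions3d(self) -> np.ndarray:
        return np.stack([e.position3d for e in self.electrodes])

    @property
    def positions2d(self) -> np.ndarray:
        if any(e.position2d is None for e in self.electrodes):
            raise ValueError("montage has no 2D positions; call project_azimuthal first")
        return np.stack([e.position2d for e in self.electrodes])

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"electrode label {label!r} not in montage") from None

    def subset(self, labels: list[str] | tuple[str, ...], name: str | None = None) -> "Montage":
        """Restrict to ``labels``, preserving this montage's channel order."""
        missing = [lb for lb in labels if lb not in self.labels]
        if missing:
            raise KeyError(f"electrode label(s) not in montage: {missing}")
        keep = set(labels)
        kept = tuple(e for e in self.electrodes if e.label in keep)
        return Montage(kept, name=name or f"{self.name}-subset")


def _position3d(alpha_deg: float, beta_deg: float) -> np.ndarray:
    a, b = np.deg2rad(alpha_deg), np.deg2rad(beta_deg)
    # vertex (0,0,1) rotated towards the nose by alpha, then towards the left ear by beta
    return np.array([-np.cos(a) * np.sin(b), np.sin(a), np.cos(a) * np.cos(b)])


def standard_montage_22() -> Montage:
    """The 22-channel Dataset-2a layout with unit-sphere and disk positions."""
    elecs = tuple(
        Electrode(label, _position3d(a, b)) for label, a, b in _ANGLES_22
    )
    return project_azimuthal(Montage(elecs, name="standard-22"))


def project_azimuthal(montage: Montage) -> Montage:
    """Fill 2D disk positions via the azimuthal equidistant projection.

    The disk radius is proportional to the polar angle from the vertex:
    the pole maps to the origin and the equator to the unit circle.
    """
    out = []
    for e in montage.electrodes:
        p = np.asarray(e.position3d, dtype=float)
        n = np.linalg.norm(p)
        if n == 0:
            raise ValueError(f"electrode {e.label!r}: zero-norm 3D position")
        p = p / n
        theta = np.arccos(np.clip(p[2], -1.0, 1.0))
        r = theta / (np.pi / 2.0)
        rho = np.hypot(p[0], p[1])
        if rho < 1e-12:
            p2 = np.zeros(2)
        else:
            p2 = r * np.array([p[0], p[1]]) / rho
        out.append(Electrode(e.label, p, p2))
    return Montage(tuple(out), name=montage.name)


def sensorimotor_subset(montage: Montage) -> Montage:
    """The 10 electrodes over the motor-cortex region, in montage order."""
    return montage.subset(SENSORIMOTOR_LABELS, name=f"{montage.name}-sensorimotor")


def save_montage(montage: Montage, path) -> None:
    """Serialize as a plain-text table: label, x, y, z (tab separated)."""
    with open(path, "w") as fh:
        fh.write("label\tx\ty\tz\n")
        for e in montage.electrodes:
            x, y, z = e.position3d
            fh.write(f"{e.label}\t{x:.12f}\t{y:.12f}\t{z:.12f}\n")


def load_montage(path, name: str = "loaded") -> Montage:
    """Read a montage table written by :func:`save_montage` and project it."""
    elecs = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("label"):
            raise ValueError("montage table must start with a 'label\\tx\\ty\\tz' header")
        for line in fh:
            if not line.strip():
                continue
            label, x, y, z = line.split("\t")
            elecs.append(Electrode(label, np.array([float(x), float(y), float(z)])))
    return project_azimuthal(Montage(tuple(elecs), name=name))
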