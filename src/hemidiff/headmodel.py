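"""EEG forward modelling on a three-shell spherical head.

The forward problem maps cortical current dipoles to scalp potentials through
a gain (leadfield) matrix ``L``: ``y = L x + noise``.  Here ``L`` is computed
analytically for three concentric spheres (brain, skull, scalp) by expanding
the dipole potential in Legendre polynomials and matching potential and radial
current density at each interface.  An import path for externally computed
leadfields (e.g. from a BEM tool) is provided as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SensorArray",
    "SourceSpace",
    "Leadfield",
    "EEGMMIDB_CHANNELS",
    "EXCLUDED_1010_CHANNELS",
    "default_montage",
    "make_source_space",
    "three_sphere_leadfield",
    "load_leadfield",
]

#: Default shell outer radii in metres: brain/cortex, skull, scalp.
DEFAULT_RADII = (0.08, 0.085, 0.092)

#: Default shell conductivities in S/m (standard 1:1/80:1 skull ratio).
DEFAULT_CONDUCTIVITIES = (0.33, 0.0042, 0.33)

#: The 64 channels of the 10-10 motor-imagery montage, in recording order.
EEGMMIDB_CHANNELS = (
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FT8", "T7", "T8", "T9", "T10", "TP7", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
)

#: 10-10 electrodes deliberately absent from the 64-channel montage.
EXCLUDED_1010_CHANNELS = (
    "Nz", "F9", "F10", "FT9", "FT10", "A1", "A2", "TP9", "TP10", "P9", "P10",
)


@dataclass
class SensorArray:
    """EEG electrodes on the scalp sphere.

    positions : (n_sensors, 3) float array, metres; every row has norm
        ``head_radius``.
    names : channel labels in the 10-10 nomenclature.
    head_radius : scalp sphere radius in metres.
    """

    positions: np.ndarray
    names: tuple[str, ...]
    head_radius: float = DEFAULT_RADII[2]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.names = tuple(self.names)
        if self.positions.shape != (len(self.names), 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.names)} channel names"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        radii = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(radii, self.head_radius, rtol=1e-9):
            raise ValueError("all sensors must lie on the scalp sphere")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class SourceSpace:
    """Dipole positions/orientations inside the cortex sphere.

    Orientations are fixed unit vectors; the default construction uses radial
    orientations, the spherical-model counterpart of dipoles perpendicular to
    the cortical surface.
    """

    positions: np.ndarray
    orientations: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        if self.positions.shape != self.orientations.shape or self.positions.ndim != 2:
            raise ValueError("positions and orientations must be matching (n, 3) arrays")
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, rtol=1e-9):
            raise ValueError("orientations must be unit vectors")

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass
class Leadfield:
    """Gain matrix in volts per (ampere metre), sensors x sources."""

    gain: np.ndarray
    sensors: SensorArray
    sources: SourceSpace | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 2:
            raise ValueError("gain must be a 2-D matrix")
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("gain contains non-finite entries")
        if self.gain.shape[0] != len(self.sensors):
            raise ValueError(
                f"gain has {self.gain.shape[0]} rows but sensor array has "
                f"{len(self.sensors)} channels"
            )
        if self.sources is not None and self.gain.shape[1] != len(self.sources):
            raise ValueError("gain column count does not match source space")

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


def _mirror_partner(name: str) -> str | None:
    """Mirror electrode label across the mid-sagittal plane (C3 -> C4)."""
    i = len(name)
    while i > 0 and name[i - 1].isdigit():
        i -= 1
    if i == len(name):  # no trailing number -> midline ('z') label
        return None
    base, num = name[:i], int(name[i:])
    partner = num + 1 if num % 2 == 1 else num - 1
    return f"{base}{partner}"


def default_montage(head_radius: float = DEFAULT_RADII[2]) -> SensorArray:
    """The 64-channel 10-10 montage projected onto the scalp sphere.

    Electrode directions come from the standard 10-05 template positions and
    are made exactly left/right symmetric: each lateral electrode is averaged
    with the mirror image of its partner (C3 with mirrored C4, ...) and
    midline electrodes are pinned to the mid-sagittal plane.
    """
    import mne

    with warnings.catch_warnings():
        # montage template naming is in flux across mne releases
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    unit = {}
    for name in EEGMMIDB_CHANNELS:
        p = np.asarray(pos[name], dtype=float)
        unit[name] = p / np.linalg.norm(p)
    sym = {}
    for name in EEGMMIDB_CHANNELS:
        partner = _mirror_partner(name)
        if partner is None:
            p = unit[name].copy()
            p[0] = 0.0
        else:
            q = unit[partner] * np.array([-1.0, 1.0, 1.0])
            p = 0.5 * (unit[name] + q)
        sym[name] = p / np.linalg.norm(p)
    positions = np.array([sym[name] for name in EEGMMIDB_CHANNELS]) * head_radius
    return SensorArray(positions=positions, names=EEGMMIDB_CHANNELS,
                       head_radius=head_radius)


def make_source_space(
    n_vertices: int = 2000,
    radius: float = 0.078,
    max_colatitude_deg: float = 120.0,
) -> SourceSpace:
    """Quasi-uniform radial-dipole grid on a spherical cortex cap.

    Vertices are placed on latitude rings with an even number of equally
    spaced longitudes per ring, which makes the grid exactly symmetric under
    left/right (x -> -x) and front/back (y -> -y) mirroring.  The cap extends
    from the vertex down to ``max_colatitude_deg`` so that inferior-temporal
    positions under the lateral electrodes are covered.
    """
    if n_vertices < 1:
        raise ValueError("n_vertices must be positive")
    theta_max = np.deg2rad(max_colatitude_deg)
    cap_area = 2.0 * np.pi * (1.0 - np.cos(theta_max))
    h = np.sqrt(cap_area / n_vertices)  # target inter-vertex spacing (radians)
    n_rings = max(1, int(round(theta_max / h)))
    points = []
    for i in range(n_rings):
        theta = (i + 0.5) * theta_max / n_rings
        m = 2 * max(1, int(round(np.pi * np.sin(theta) / h)))
        phi = 2.0 * np.pi * np.arange(m) / m
        st, ct = np.sin(theta), np.cos(theta)
        ring = np.column_stack([st * np.cos(phi), st * np.sin(phi),
                                np.full(m, ct)])
        points.append(ring)
    unit = np.concatenate(points, axis=0)
    return SourceSpace(positions=unit * radius, orientations=unit.copy())


def _shell_factors(
    n_max: int,
    radii: tuple[float, float, float],
    conductivities: tuple[float, float, float],
) -> np.ndarray:
    """Per-order surface amplification factors of the three-shell model.

    For each Legendre order n the potential in shell j is
    ``A_j rho^n + B_j rho^-(n+1)`` (radii normalised by the scalp radius),
    with the unit-amplitude primary dipole term ``rho^-(n+1)`` added in the
    innermost shell.  Matching V and sigma dV/drho at both interfaces and
    imposing zero radial current at the scalp gives a 5x5 linear system; the
    returned factor is the total surface coefficient ``A_3 + B_3``.  In the
    homogeneous limit (equal conductivities) the factor is (2n+1)/n.
    """
    r1, r2, r3 = radii
    s1, s2, s3 = conductivities
    rho1, rho2 = r1 / r3, r2 / r3
    factors = np.empty(n_max + 1)
    factors[0] = 0.0
    for n in range(1, n_max + 1):
        p1n, p1i = rho1 ** n, rho1 ** -(n + 1)
        p2n, p2i = rho2 ** n, rho2 ** -(n + 1)
        # unknowns: A1, A2, B2, A3, B3
        A = np.array([
            [p1n, -p1n, -p1i, 0.0, 0.0],
            [s1 * n * p1n, -s2 * n * p1n, s2 * (n + 1) * p1i, 0.0, 0.0],
            [0.0, p2n, p2i, -p2n, -p2i],
            [0.0, s2 * n * p2n, -s2 * (n + 1) * p2i,
             -s3 * n * p2n, s3 * (n + 1) * p2i],
            [0.0, 0.0, 0.0, n, -(n + 1)],
        ])
        b = np.array([-p1i, s1 * (n + 1) * p1i, 0.0, 0.0, 0.0])
        sol = np.linalg.solve(A, b)
        factors[n] = sol[3] + sol[4]
    return factors


def three_sphere_leadfield(
    sensors: SensorArray,
    sources: SourceSpace,
    radii: tuple[float, float, float] = DEFAULT_RADII,
    conductivities: tuple[float, float, float] = DEFAULT_CONDUCTIVITIES,
    n_terms: int = 60,
    average_reference: bool = True,
) -> Leadfield:
    """Analytic EEG leadfield for three concentric spherical shells.

    Each column holds the scalp potentials of one unit current dipole
    (1 A.m).  The Legendre series is truncated at ``n_terms``; if the last
    term is still larger than 1e-10 of the accumulated potential a warning
    reports the achieved tolerance (shallow sources converge slowly).
    """
    if not (radii[0] < radii[1] < radii[2]):
        raise ValueError("radii must be strictly increasing (brain, skull, scalp)")
    if min(conductivities) <= 0:
        raise ValueError("conductivities must be positive")
    if n_terms < 20:
        raise ValueError("n_terms must be at least 20")
    if abs(sensors.head_radius - radii[2]) > 1e-12 * radii[2]:
        raise ValueError("sensor array radius must equal the scalp radius")
    src_r = np.linalg.norm(sources.positions, axis=1)
    if np.any(src_r >= radii[0]):
        bad = int(np.argmax(src_r >= radii[0]))
        raise ValueError(
            f"source {bad} lies at radius {src_r[bad]:.4g} m, outside the "
            f"inner sphere ({radii[0]:.4g} m)"
        )

    R = radii[2]
    sensor_unit = sensors.positions / R  # (S, 3)
    with np.errstate(invalid="ignore"):
        src_unit = np.where(src_r[:, None] > 0,
                            sources.positions / np.maximum(src_r, 1e-300)[:, None],
                            np.array([0.0, 0.0, 1.0]))
    m = sources.orientations
    t = src_r / R  # (P,)
    u = sensor_unit @ src_unit.T        # cos(angle sensor, source), (S, P)
    u = np.clip(u, -1.0, 1.0)
    m_r = np.einsum("pi,pi->p", m, src_unit)      # radial moment component
    m_s = sensor_unit @ m.T                        # (S, P): m . sensor_unit
    tang = m_s - u * m_r[None, :]  # equals m_t * sin(gamma); no 1/sin needed

    factors = _shell_factors(n_terms, radii, conductivities)

    # Legendre recurrences: P_n and P'_n on the (S, P) angle grid.
    P_prev = np.ones_like(u)       # P_0
    P_cur = u.copy()               # P_1
    dP_prev = np.zeros_like(u)     # P'_0
    dP_cur = np.ones_like(u)       # P'_1
    V = np.zeros_like(u)
    t_pow = np.ones_like(t)        # t^(n-1), starts at n=1
    last_term_max = 0.0
    for n in range(1, n_terms + 1):
        term = factors[n] * t_pow[None, :] * (
            n * m_r[None, :] * P_cur + tang * dP_cur
        )
        V += term
        if n == n_terms:
            last_term_max = float(np.max(np.abs(term)))
        t_pow = t_pow * t
        # advance recurrences to n+1
        P_next = ((2 * n + 1) * u * P_cur - n * P_prev) / (n + 1)
        dP_next = dP_prev + (2 * n + 1) * P_cur
        P_prev, P_cur = P_cur, P_next
        dP_prev, dP_cur = dP_cur, dP_next

    scale = 1.0 / (4.0 * np.pi * conductivities[0] * R ** 2)
    gain = scale * V
    vmax = float(np.max(np.abs(gain)))
    if vmax > 0 and scale * last_term_max / vmax > 1e-10:
        warnings.warn(
            "Legendre series not fully converged at "
            f"n_terms={n_terms}: last-term relative size "
            f"{scale * last_term_max / vmax:.2e} (> 1e-10); "
            "increase n_terms for shallow sources",
            RuntimeWarning,
            stacklevel=2,
        )
    if average_reference:
        gain = gain - gain.mean(axis=0, keepdims=True)
    return Leadfield(
        gain=gain,
        sensors=sensors,
        sources=sources,
        meta={
            "model": "three_sphere",
            "radii": tuple(radii),
            "conductivities": tuple(conductivities),
            "n_terms": n_terms,
            "average_reference": average_reference,
        },
    )


def load_leadfield(
    path,
    sensors: SensorArray,
    n_sources: int,
    delimiter: str | None = None,
    transpose: bool = False,
    average_reference: bool = False,
) -> Leadfield:
    """Load an externally computed leadfield from a delimited text matrix.

    The file must contain ``n_sensors x n_sources`` numbers (or the transpose
    with ``transpose=True``).  Non-numeric cells are reported with their
    row/column position.
    """
    try:
        gain = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError:
        with open(path) as fh:
            for i, line in enumerate(fh):
                cells = line.split(delimiter) if delimiter else line.split()
                for j, cell in enumerate(cells):
                    try:
                        float(cell)
                    except ValueError:
                        raise ValueError(
                            f"{path}: non-numeric cell at row {i + 1}, "
                            f"column {j + 1}: {cell!r}"
                        ) from None
        raise
    if transpose:
        gain = gain.T
    expected = (len(sensors), n_sources)
    if gain.shape != expected:
        raise ValueError(
            f"{path}: expected leadfield of shape {expected}, found {gain.shape}"
        )
    if average_reference:
        gain = gain - gain.mean(axis=0, keepdims=True)
    return Leadfield(gain=gain, sensors=sensors, sources=None,
                     meta={"model": "imported", "path": str(path),
                           "average_reference": average_reference})
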