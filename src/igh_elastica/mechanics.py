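"""Forward mechanics of modular Ig/helix filaments under AFM-style pulling.

The filament is a serial chain of mechanical elements sharing one force:

* unfolded polypeptide stretches as a worm-like chain (WLC, Marko-Siggia
  interpolation) with persistence length 0.5 nm;
* folded Ig domains unfold stochastically and irreversibly (on the
  timescale of one pull) with a Bell-Evans force-activated rate,
  releasing a contour-length gain dL;
* helical linkers unfold reversibly and close to equilibrium, so their
  state is drawn from the two-state Boltzmann occupancy at the current
  force; around their midpoint force (~30 pN) this produces a force
  plateau in the force-extension curve.

``simulate_pull`` drives a constant-velocity stage against the chain
through a cantilever spring, solving the quasi-static force balance
``stage = force/stiffness + molecular_extension`` at every sample, and
emits a force-extension trace with Gaussian force noise added after the
mechanics (so event logic is noise-free).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "KB",
    "WLCParams",
    "RigidSegment",
    "HelixElement",
    "IgElement",
    "PullingProtocol",
    "ForceExtensionTrace",
    "wlc_force",
    "wlc_extension",
    "serial_chain_extension",
    "helix_unfolded_fraction",
    "bell_evans_rate",
    "simulate_pull",
    "myomesin_chain",
    "myomesin_arm",
]

#: Boltzmann constant in pN nm / K (kT = 4.114 pN nm at 298 K).
KB = 4.114 / 298.0


def thermal_energy(temperature: float = 298.0) -> float:
    """kT in pN nm."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    return KB * temperature


# ---------------------------------------------------------------------------
# Worm-like chain (Marko-Siggia interpolation)


def _phi(f):
    """Dimensionless WLC force F*p/kT as a function of relative extension f."""
    return f + 0.25 / (1.0 - f) ** 2 - 0.25


def _phi_prime(f):
    return 1.0 + 0.5 / (1.0 - f) ** 3


def _phi_inv(phi):
    """Relative extension f in [0, 1) solving _phi(f) = phi (vectorized).

    Safeguarded Newton iteration; phi is convex and strictly increasing
    on [0, 1), so clipped Newton converges for any non-negative phi.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0):
        raise ValueError("dimensionless force must be >= 0")
    # initial guess: low-force linear regime vs high-force 1/(2 sqrt(phi)) tail
    with np.errstate(divide="ignore"):
        f = np.where(phi < 1.0, 2.0 * phi / 3.0, 1.0 - 0.5 / np.sqrt(np.maximum(phi, 1.0)))
    f = np.clip(f, 0.0, 1.0 - 1e-12)
    for _ in range(200):
        g = _phi(f) - phi
        f = np.clip(f - g / _phi_prime(f), 0.0, 1.0 - 1e-12)
        if np.max(np.abs(g)) < 1e-13 * max(1.0, float(np.max(phi))):
            break
    return f if f.ndim else float(f)


@dataclass(frozen=True)
class WLCParams:
    """Worm-like chain parameters: persistence length and contour length (nm)."""

    persistence_length: float = 0.5
    contour_length: float = 1.0
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if self.persistence_length <= 0 or self.contour_length <= 0:
            raise ValueError("persistence and contour lengths must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")


def wlc_force(extension, params: WLCParams):
    """Marko-Siggia WLC force (pN) at the given extension (nm).

    F = (kT/p) * [x/L + 1/(4 (1-x/L)^2) - 1/4]; monotone increasing in x
    and divergent as x -> L.  Extensions must satisfy 0 <= x < L.
    """
    x = np.asarray(extension, dtype=float)
    if np.any(x < 0) or np.any(x >= params.contour_length):
        raise ValueError("extension must lie in [0, contour_length)")
    f = x / params.contour_length
    out = thermal_energy(params.temperature) / params.persistence_length * _phi(f)
    return out if out.ndim else float(out)


def wlc_extension(force, params: WLCParams):
    """Inverse of :func:`wlc_force`: extension (nm) at the given force (pN)."""
    F = np.asarray(force, dtype=float)
    if np.any(F < 0):
        raise ValueError("force must be >= 0")
    phi = F * params.persistence_length / thermal_energy(params.temperature)
    out = params.contour_length * _phi_inv(phi)
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# Chain elements

FOLDED_MODES = ("contour", "rigid")


@dataclass
class RigidSegment:
    """A passive element that never unfolds (e.g. the central dimerization module)."""

    extent: float  # nm
    folded_mode: str = "contour"
    label: str = ""

    def __post_init__(self) -> None:
        if self.extent < 0:
            raise ValueError("extent must be >= 0")
        if self.folded_mode not in FOLDED_MODES:
            raise ValueError(f"folded_mode must be one of {FOLDED_MODES}")


@dataclass
class HelixElement:
    """Reversible two-state helical linker with an equilibrium midpoint force.

    ``contour_gain_unfolded`` is the contour-length gain (nm) released on
    unfolding; ``midpoint_force`` is the force at which folded and
    unfolded states are equally occupied.  ``attempt_frequency`` (1/s)
    sets the transition kinetics: unfolding and refolding rates are
    ``nu * p`` and ``nu * (1 - p)`` with p the equilibrium occupancy at
    the current force, which satisfies detailed balance and relaxes to
    equilibrium much faster than the stage moves.  ``folded_extent`` is
    the contribution of the folded helix to the chain, counted either as
    WLC contour ("contour", default) or as a fixed axial extent
    ("rigid").
    """

    residue_count: int = 20
    contour_gain_unfolded: float = 6.0
    midpoint_force: float = 30.0
    attempt_frequency: float = 1e4
    folded_extent: float = 2.25
    folded_mode: str = "contour"
    state: str = "folded"
    label: str = ""

    def __post_init__(self) -> None:
        if self.contour_gain_unfolded <= 0:
            raise ValueError("contour_gain_unfolded must be > 0")
        if self.midpoint_force <= 0:
            raise ValueError("midpoint_force must be > 0")
        if self.attempt_frequency <= 0:
            raise ValueError("attempt_frequency must be > 0")
        if self.folded_extent < 0:
            raise ValueError("folded_extent must be >= 0")
        if self.folded_mode not in FOLDED_MODES:
            raise ValueError(f"folded_mode must be one of {FOLDED_MODES}")
        if self.state not in ("folded", "unfolded"):
            raise ValueError("state must be 'folded' or 'unfolded'")


@dataclass
class IgElement:
    """Ig domain with Bell-Evans stochastic, irreversible unfolding.

    ``contour_gain_unfolded`` is the contour-length increment dL (nm)
    measured between successive WLC fits when the domain unfolds; ``k0``
    (1/s) and ``delta_x`` (nm) are the zero-force unfolding rate and the
    distance to the transition state.  ``k0 = 0`` disables unfolding.
    The defaults (94 residues, folded extent 4.61 nm, dL 29.7 nm) satisfy
    dL = residues * 0.365 nm - folded_extent.
    """

    residue_count: int = 94
    contour_gain_unfolded: float = 29.7
    k0: float = 1e-4
    delta_x: float = 0.3
    folded_extent: float = 4.61
    folded_mode: str = "contour"
    state: str = "folded"
    label: str = ""

    def __post_init__(self) -> None:
        if self.contour_gain_unfolded <= 0:
            raise ValueError("contour_gain_unfolded (dL) must be > 0")
        if self.k0 < 0:
            raise ValueError("k0 must be >= 0 (0 disables unfolding)")
        if self.delta_x <= 0:
            raise ValueError("delta_x must be > 0")
        if self.folded_extent < 0:
            raise ValueError("folded_extent must be >= 0")
        if self.folded_mode not in FOLDED_MODES:
            raise ValueError(f"folded_mode must be one of {FOLDED_MODES}")
        if self.state not in ("folded", "unfolded"):
            raise ValueError("state must be 'folded' or 'unfolded'")


ChainElement = RigidSegment | HelixElement | IgElement


def _element_contributions(elem: ChainElement) -> tuple[float, float]:
    """(WLC contour nm, rigid extent nm) contributed by one element now."""
    if isinstance(elem, RigidSegment):
        return (elem.extent, 0.0) if elem.folded_mode == "contour" else (0.0, elem.extent)
    if elem.state == "unfolded":
        return (elem.folded_extent + elem.contour_gain_unfolded, 0.0)
    if elem.folded_mode == "contour":
        return (elem.folded_extent, 0.0)
    return (0.0, elem.folded_extent)


def serial_chain_extension(
    force: float,
    elements: Sequence[ChainElement],
    persistence: float = 0.5,
    temperature: float = 298.0,
):
    """Extension (nm) of the serial chain at a common force (pN).

    All WLC contour in the chain stretches with the same relative
    extension, so the chain extends as one WLC of the summed contour
    length plus the summed rigid extents.
    """
    L = C = 0.0
    for elem in elements:
        dl, dc = _element_contributions(elem)
        L += dl
        C += dc
    Fa = np.asarray(force, dtype=float)
    if np.any(Fa < 0):
        raise ValueError("force must be >= 0")
    if L == 0.0:
        out = np.full_like(Fa, C)
        return out if out.ndim else float(out)
    phi = Fa * persistence / thermal_energy(temperature)
    out = C + L * _phi_inv(phi)
    return out if np.ndim(out) else float(out)


def helix_unfolded_fraction(
    force: float,
    elem: HelixElement,
    persistence: float = 0.5,
    temperature: float = 298.0,
) -> float:
    """Equilibrium unfolded occupancy of a two-state helix at a force.

    Boltzmann occupancy 1/(1 + exp(-(F - F_1/2) dL_eff / kT)) with
    dL_eff the extension gained by unfolding at the midpoint force, so
    the occupancy is exactly 0.5 at F = midpoint_force.
    """
    if force < 0:
        raise ValueError("force must be >= 0")
    kT = thermal_energy(temperature)
    f_mid = _phi_inv(elem.midpoint_force * persistence / kT)
    if elem.folded_mode == "contour":
        dl_eff = elem.contour_gain_unfolded * f_mid
    else:
        dl_eff = (elem.folded_extent + elem.contour_gain_unfolded) * f_mid - elem.folded_extent
    if dl_eff <= 0:
        raise ValueError("midpoint extension gain must be positive")
    arg = -(force - elem.midpoint_force) * dl_eff / kT
    if arg > 700:
        return 0.0
    return 1.0 / (1.0 + math.exp(arg))


def bell_evans_rate(
    force: float, k0: float, delta_x: float, temperature: float = 298.0
) -> float:
    """Bell-Evans force-activated rate k0 * exp(F dx / kT) in 1/s."""
    if force < 0:
        raise ValueError("force must be >= 0")
    return k0 * math.exp(force * delta_x / thermal_energy(temperature))


# ---------------------------------------------------------------------------
# Pulling protocol and trace containers


@dataclass(frozen=True)
class PullingProtocol:
    """Constant-velocity stage schedule with cantilever coupling and noise.

    ``segments`` is an ordered list of (stage_start_nm, stage_end_nm,
    speed_nm_per_s); decreasing segments are relaxation phases.  The
    cantilever stiffness (pN/nm) couples the stage to the molecule:
    stage = deflection + extension with deflection = force/stiffness.
    """

    segments: tuple[tuple[float, float, float], ...]
    sampling_rate: float = 20_000.0
    cantilever_stiffness: float = 6.0
    force_noise_sd: float = 3.0
    seed: int | None = None

    def __init__(
        self,
        segments: Iterable[tuple[float, float, float]],
        sampling_rate: float = 20_000.0,
        cantilever_stiffness: float = 6.0,
        force_noise_sd: float = 3.0,
        seed: int | None = None,
    ) -> None:
        segs = tuple((float(a), float(b), float(v)) for a, b, v in segments)
        if not segs:
            raise ValueError("protocol needs at least one segment")
        for a, b, v in segs:
            if v <= 0:
                raise ValueError("segment speeds must be > 0")
            if a == b:
                raise ValueError("segment must move the stage")
        if sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if cantilever_stiffness <= 0:
            raise ValueError("cantilever_stiffness must be > 0")
        if force_noise_sd < 0:
            raise ValueError("force_noise_sd must be >= 0")
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "sampling_rate", float(sampling_rate))
        object.__setattr__(self, "cantilever_stiffness", float(cantilever_stiffness))
        object.__setattr__(self, "force_noise_sd", float(force_noise_sd))
        object.__setattr__(self, "seed", seed)

    @classmethod
    def constant_velocity(cls, distance: float, speed: float, **kw) -> "PullingProtocol":
        return cls([(0.0, distance, speed)], **kw)

    @classmethod
    def stretch_relax(cls, distance: float, speed: float, **kw) -> "PullingProtocol":
        return cls([(0.0, distance, speed), (distance, 0.0, speed)], **kw)


@dataclass
class ForceExtensionTrace:
    """Sampled pulling record: time (s), stage (nm), extension (nm), force (pN)."""

    time: np.ndarray
    stage_position: np.ndarray
    molecular_extension: np.ndarray
    force: np.ndarray
    events: list[tuple[float, str, str]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("stage_position", "molecular_extension", "force"):
            if len(getattr(self, name)) != n:
                raise ValueError("trace arrays must have equal length")
        if n > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if n:
            t0, t1 = self.time[0], self.time[-1]
            for t, _, _ in self.events:
                if not (t0 <= t <= t1):
                    raise ValueError("event log times must lie within the trace span")

    def __len__(self) -> int:
        return len(self.time)


# ---------------------------------------------------------------------------
# Simulation


class _UniformBuffer:
    """Chunked uniform variates so the inner loop avoids per-draw RNG calls."""

    def __init__(self, rng: np.random.Generator, chunk: int = 1 << 16) -> None:
        self._rng = rng
        self._chunk = chunk
        self._buf = rng.random(chunk)
        self._i = 0

    def next(self) -> float:
        if self._i >= self._chunk:
            self._buf = self._rng.random(self._chunk)
            self._i = 0
        u = self._buf[self._i]
        self._i += 1
        return u


def simulate_pull(
    elements: Sequence[ChainElement],
    protocol: PullingProtocol,
    persistence: float = 0.5,
    temperature: float = 298.0,
    rng: np.random.Generator | None = None,
    log_helix_events: bool = False,
    helix_update: str = "kinetic",
) -> ForceExtensionTrace:
    """Simulate one constant-velocity pull and return the sampled trace.

    At each time step the stage advances by speed/sampling_rate; helix
    states are updated stochastically at the force of the previous step;
    the quasi-static balance
    ``stage = force/stiffness + extension(force)`` is then solved for the
    force (Newton iteration on the chain's relative extension, residual
    < 1e-6 pN); finally each folded Ig unfolds with probability
    1 - exp(-k(F) dt).  Gaussian force noise is added to the emitted
    force after the mechanics, so transitions are driven by the clean
    force.  Ig unfolding is irreversible within a trace; helix elements
    may toggle arbitrarily often.

    ``helix_update`` selects the near-equilibrium scheme:

    * "kinetic" (default): each helix flips with probability
      1 - exp(-k dt), k = nu*p for unfolding and nu*(1-p) for refolding
      (p = equilibrium occupancy at the current force, nu the helix's
      attempt frequency).  Detailed balance holds at fixed force and
      transitions are predominantly single-helix flips, producing the
      experimentally observed rapid flicker between adjacent contour
      levels around the plateau.
    * "equilibrium": every helix state is redrawn independently from its
      occupancy each step (the nu*dt >> 1 limit).  With several helices
      sharing one force this exaggerates collective fluctuations and is
      kept for comparison only.

    The input elements are not mutated; final states are reported in
    ``metadata["final_states"]``.
    """
    if helix_update not in ("kinetic", "equilibrium"):
        raise ValueError("helix_update must be 'kinetic' or 'equilibrium'")
    if rng is None:
        rng = np.random.default_rng(protocol.seed)
    elems = [replace(e) for e in elements]

    kT = thermal_energy(temperature)
    kp = kT / persistence  # pN, force scale of the WLC
    k_c = protocol.cantilever_stiffness
    dt = 1.0 / protocol.sampling_rate

    # aggregate contour (L, nm of WLC) and rigid extent (C, nm)
    L = C = 0.0
    for e in elems:
        dl, dc = _element_contributions(e)
        L += dl
        C += dc

    helices = [e for e in elems if isinstance(e, HelixElement)]
    igs = [e for e in elems if isinstance(e, IgElement)]
    for i, e in enumerate(helices):
        if not e.label:
            e.label = f"helix_{i}"
    for i, e in enumerate(igs):
        if not e.label:
            e.label = f"ig_{i}"

    # per-helix precomputation: logistic slope dL_eff/kT and contour deltas
    h_mid = []
    h_slope = []
    h_dL = []  # contour gained on unfolding
    h_dC = []  # rigid extent lost on unfolding (rigid mode only)
    for e in helices:
        f_mid = float(_phi_inv(e.midpoint_force * persistence / kT))
        if e.folded_mode == "contour":
            dl_eff = e.contour_gain_unfolded * f_mid
            h_dL.append(e.contour_gain_unfolded)
            h_dC.append(0.0)
        else:
            dl_eff = (e.folded_extent + e.contour_gain_unfolded) * f_mid - e.folded_extent
            h_dL.append(e.folded_extent + e.contour_gain_unfolded)
            h_dC.append(e.folded_extent)
        if dl_eff <= 0:
            raise ValueError(
                f"helix {e.label!r}: midpoint extension gain must be positive"
            )
        h_mid.append(e.midpoint_force)
        h_slope.append(dl_eff / kT)

    ig_dL = []
    ig_dC = []
    for e in igs:
        if e.folded_mode == "contour":
            ig_dL.append(e.contour_gain_unfolded)
            ig_dC.append(0.0)
        else:
            ig_dL.append(e.folded_extent + e.contour_gain_unfolded)
            ig_dC.append(e.folded_extent)

    n_total = 0
    seg_steps = []
    for a, b, v in protocol.segments:
        n = max(1, int(round(abs(b - a) / v * protocol.sampling_rate)))
        seg_steps.append(n)
        n_total += n

    time = np.empty(n_total)
    stage = np.empty(n_total)
    ext = np.empty(n_total)
    force = np.empty(n_total)
    events: list[tuple[float, str, str]] = []
    helix_toggles = dict.fromkeys((e.label for e in helices), 0)

    uni = _UniformBuffer(rng)
    exp = math.exp
    kinetic = helix_update == "kinetic"
    F = 0.0
    f = 0.0  # relative extension of the chain's WLC content
    t = 0.0
    i_out = 0
    max_residual = 0.0

    for (a, b, v), n in zip(protocol.segments, seg_steps):
        direction = 1.0 if b > a else -1.0
        ds = direction * v * dt
        s = a
        for _ in range(n):
            s += ds
            t += dt

            # stochastic helix update at the last force (near-equilibrium)
            for j, e in enumerate(helices):
                arg = (F - h_mid[j]) * h_slope[j]
                if arg < -30.0:
                    p_unf = 0.0
                elif arg > 30.0:
                    p_unf = 1.0
                else:
                    p_unf = 1.0 / (1.0 + exp(-arg))
                was_unf = e.state == "unfolded"
                if kinetic:
                    rate = e.attempt_frequency * (1.0 - p_unf if was_unf else p_unf)
                    if rate <= 0.0:
                        continue
                    p_flip = -math.expm1(-rate * dt)
                    new_unf = (not was_unf) if uni.next() < p_flip else was_unf
                else:
                    if p_unf <= 0.0:
                        new_unf = False
                    elif p_unf >= 1.0:
                        new_unf = True
                    else:
                        new_unf = uni.next() < p_unf
                if new_unf != was_unf:
                    if new_unf:
                        e.state = "unfolded"
                        L += h_dL[j]
                        C -= h_dC[j]
                        kind = "unfold"
                    else:
                        e.state = "folded"
                        L -= h_dL[j]
                        C += h_dC[j]
                        kind = "refold"
                    helix_toggles[e.label] += 1
                    if log_helix_events:
                        events.append((t, e.label, kind))

            # quasi-static force balance: s = F/k_c + C + L * f(F)
            if L <= 0.0:
                F = k_c * (s - C)
                if F < 0.0:
                    F = 0.0
                x = s - F / k_c
            else:
                target = s - C
                if target <= 0.0:
                    F = 0.0
                    f = 0.0
                    x = s
                else:
                    # Newton on relative extension f: g(f) = kp*phi(f)/k_c + L*f - target
                    if f <= 0.0:
                        f = min(0.5, target / L * 0.5)
                    for _ in range(80):
                        om = 1.0 - f
                        phi = f + 0.25 / (om * om) - 0.25
                        g = kp * phi / k_c + L * f - target
                        gp = kp * (1.0 + 0.5 / (om * om * om)) / k_c + L
                        step = g / gp
                        f -= step
                        if f < 0.0:
                            f = 0.0
                        elif f > 0.999999999:
                            f = 0.999999999
                        if abs(g) < 1e-9:
                            break
                    om = 1.0 - f
                    F = kp * (f + 0.25 / (om * om) - 0.25)
                    if F < 0.0:
                        F = 0.0
                    x = C + L * f
                    resid = abs(s - F / k_c - x)
                    if resid > max_residual:
                        max_residual = resid

            # stochastic, irreversible Ig unfolding at the clean force
            for j, e in enumerate(igs):
                if e.state == "folded" and e.k0 > 0.0:
                    rate = e.k0 * exp(F * e.delta_x / kT)
                    p_unf = -math.expm1(-rate * dt)
                    if p_unf > 0.0 and uni.next() < p_unf:
                        e.state = "unfolded"
                        L += ig_dL[j]
                        C -= ig_dC[j]
                        events.append((t, e.label, "unfold"))

            time[i_out] = t
            stage[i_out] = s
            ext[i_out] = x
            force[i_out] = F
            i_out += 1

    if protocol.force_noise_sd > 0:
        force = force + rng.normal(0.0, protocol.force_noise_sd, n_total)

    metadata = {
        "protocol": {
            "segments": [list(seg) for seg in protocol.segments],
            "sampling_rate": protocol.sampling_rate,
            "cantilever_stiffness": protocol.cantilever_stiffness,
            "force_noise_sd": protocol.force_noise_sd,
            "seed": protocol.seed,
        },
        "persistence": persistence,
        "temperature": temperature,
        "final_states": {
            e.label: e.state for e in elems if not isinstance(e, RigidSegment)
        },
        "helix_toggle_counts": helix_toggles,
        "max_balance_residual_nm": max_residual,
        "max_balance_residual_pN": max_residual * k_c,
    }
    return ForceExtensionTrace(time, stage, ext, force, events, metadata)


# ---------------------------------------------------------------------------
# Canonical chains


def myomesin_chain(
    n_ig: int = 8,
    n_helix: int = 8,
    ig_dL: float = 29.7,
    helix_gain: float = 6.0,
    midpoint_force: float = 30.0,
    k0: float = 1e-4,
    delta_x: float = 0.3,
    central_extent: float = 4.0,
    folded_mode: str = "contour",
) -> list[ChainElement]:
    """Full tail-to-tail dimer chain as pulled between the two distal domains.

    Eight unfoldable Ig domains and eight helical linkers flank the
    central dimerization module, which is treated as a passive segment.
    Elements alternate Ig/helix from one end, mirror-symmetrically about
    the center.
    """
    half_ig = n_ig // 2
    half_h = n_helix // 2
    chain: list[ChainElement] = []

    def arm(prefix: str) -> list[ChainElement]:
        out: list[ChainElement] = []
        for i in range(max(half_ig, half_h)):
            if i < half_ig:
                out.append(
                    IgElement(
                        contour_gain_unfolded=ig_dL,
                        k0=k0,
                        delta_x=delta_x,
                        folded_mode=folded_mode,
                        label=f"{prefix}ig_{i}",
                    )
                )
            if i < half_h:
                out.append(
                    HelixElement(
                        contour_gain_unfolded=helix_gain,
                        midpoint_force=midpoint_force,
                        folded_mode=folded_mode,
                        label=f"{prefix}h_{i}",
                    )
                )
        return out

    chain.extend(arm("a."))
    chain.append(RigidSegment(central_extent, folded_mode=folded_mode, label="center"))
    chain.extend(reversed(arm("b.")))
    return chain


def myomesin_arm(
    n_ig: int = 5,
    n_helix: int = 4,
    ig_dL: float = 29.7,
    helix_gain: float = 6.0,
    midpoint_force: float = 30.0,
    k0: float = 1e-4,
    delta_x: float = 0.3,
    folded_mode: str = "contour",
) -> list[ChainElement]:
    """One monomer arm: Ig domains alternating with helical linkers."""
    chain: list[ChainElement] = []
    for i in range(max(n_ig, n_helix)):
        if i < n_ig:
            chain.append(
                IgElement(
                    contour_gain_unfolded=ig_dL,
                    k0=k0,
                    delta_x=delta_x,
                    folded_mode=folded_mode,
                    label=f"ig_{i}",
                )
            )
        if i < n_helix:
            chain.append(
                HelixElement(
                    contour_gain_unfolded=helix_gain,
                    midpoint_force=midpoint_force,
                    folded_mode=folded_mode,
                    label=f"h_{i}",
                )
            )
    return chain
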