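"""Monodomain electrophysiology on a wedge of myocardium.

The transmembrane voltage obeys the monodomain reaction--diffusion
equation dv/dt = div(G grad v) + I_ion(v, h), with the local conductivity
(here lumped to an effective diffusivity in mm^2/ms)
G = sigma_T I + (sigma_L - sigma_T) f f^T built from the fiber field f.
The membrane is a two-variable phenomenological excitable model of the
Mitchell--Schaeffer class; the dimensionless voltage v in [0, 1] maps to
millivolts as Vm = v_rest + v_amp * v.  Space is a regular lattice with
face-based (harmonic-mean) conductances and no-flux boundaries; time
stepping is explicit Euler with a stability check.

The wedge study compares three fiber configurations on the same grid:
(1) a rule-based linear transmural helix ramp, (2) the phantom fiber field
containing the apex--base bundle, (3) the same field plus a non-conducting
interface with discrete holes at the bundle border.  Outputs are local
activation time (LAT) maps, LAT-difference statistics, and unipolar /
bipolar pseudo-ECGs from an infinite-homogeneous-medium lead field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import StabilityError, substream

__all__ = [
    "MembraneParams",
    "WedgeModel",
    "EPResult",
    "make_wedge_model",
    "rule_based_fibers",
    "apply_interface",
    "run_monodomain",
    "pseudo_ecg",
    "electrode_layout",
    "compare_configurations",
    "planar_cv",
]

_FACES = {
    "left": (0, 0), "right": (0, 1),
    "front": (1, 0), "back": (1, 1),
    "bottom": (2, 0), "top": (2, 1),
}


@dataclass
class MembraneParams:
    """Two-variable excitable membrane (Mitchell--Schaeffer class).

    Time constants in ms; ``v_gate`` is the dimensionless excitation
    threshold of the gate dynamics.  ``v_rest_mv``/``v_amp_mv`` map the
    dimensionless voltage to millivolts.
    """

    tau_in: float = 0.3
    tau_out: float = 6.0
    tau_open: float = 120.0
    tau_close: float = 150.0
    v_gate: float = 0.13
    v_rest_mv: float = -80.0
    v_amp_mv: float = 100.0


@dataclass
class WedgeModel:
    """Wedge geometry, fiber field, conductivities and discretisation."""

    fibers: np.ndarray            # (nx, ny, nz, 3) unit vectors
    dx: float                     # mm, isotropic lattice spacing
    sigma_l: float = 0.12         # mm^2/ms along the fiber
    sigma_t: float = 0.03         # mm^2/ms across the fiber
    tissue: np.ndarray | None = None
    face_keep: tuple | None = None  # per-axis face multipliers (interface holes)
    membrane: MembraneParams = field(default_factory=MembraneParams)
    dt: float = 0.02              # ms
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.fibers = np.asarray(self.fibers, dtype=float)
        if self.tissue is None:
            self.tissue = np.linalg.norm(self.fibers, axis=-1) > 0.5
        self.tissue = np.asarray(self.tissue, dtype=bool)
        if self.sigma_l <= 0 or self.sigma_t <= 0:
            raise ValueError("conductivities must be positive")

    @property
    def shape(self):
        return self.fibers.shape[:3]

    def conductivity_tensors(self) -> np.ndarray:
        """G = sigma_T I + (sigma_L - sigma_T) f f^T, zero off-tissue (SPD
        on tissue since both sigmas are positive)."""
        f = self.fibers
        G = self.sigma_t * np.broadcast_to(np.eye(3), f.shape[:3] + (3, 3)).copy()
        G += (self.sigma_l - self.sigma_t) * f[..., :, None] * f[..., None, :]
        G[~self.tissue] = 0.0
        return G

    def stability_bound(self) -> float:
        """Explicit-Euler diffusion stability bound on dt (ms)."""
        return self.dx ** 2 / (6.0 * max(self.sigma_l, self.sigma_t))


def make_wedge_model(fibers, dx, sigma_l=0.12, sigma_t=0.03, tissue=None,
                     dt=0.02, membrane=None, labels=None) -> WedgeModel:
    return WedgeModel(
        fibers=np.asarray(fibers, dtype=float), dx=float(dx),
        sigma_l=float(sigma_l), sigma_t=float(sigma_t), tissue=tissue,
        membrane=membrane or MembraneParams(), dt=float(dt), labels=labels,
    )


def rule_based_fibers(shape, angle_endo: float = 60.0, angle_epi: float = -60.0,
                      transmural_axis: int = 1, tissue=None) -> np.ndarray:
    """Linear transmural helix-angle ramp (the rule-based control field).

    The helix angle varies linearly with normalised transmural depth from
    ``angle_endo`` at depth 0 to ``angle_epi`` at depth 1; fibers lie in
    the circumferential--longitudinal (x--z) plane and are unit norm.
    """
    shape = tuple(shape)
    if tissue is not None:
        tissue = np.asarray(tissue, dtype=bool)
        proj = np.any(tissue, axis=tuple(a for a in range(3) if a != transmural_axis))
        idx = np.nonzero(proj)[0]
        j0, j1 = int(idx[0]), int(idx[-1]) + 1
    else:
        j0, j1 = 0, shape[transmural_axis]
    n = max(j1 - j0, 1)
    j = np.arange(shape[transmural_axis], dtype=float)
    depth = np.clip((j - j0 + 0.5) / n, 0.0, 1.0)
    ha = np.deg2rad(angle_endo + (angle_epi - angle_endo) * depth)
    fib_1d = np.stack([np.cos(ha), np.zeros_like(ha), np.sin(ha)], axis=-1)
    expand = [None, None, None]
    expand[transmural_axis] = slice(None)
    fibers = np.zeros(shape + (3,))
    fibers[...] = fib_1d[tuple(expand) + (slice(None),)]
    if tissue is not None:
        fibers[~tissue] = 0.0
    return fibers


def _interface_faces(labels):
    """Per-axis boolean face arrays marking bundle-border faces (between a
    label-2 voxel and any other tissue voxel)."""
    labels = np.asarray(labels)
    faces = []
    for a in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[a] = slice(None, -1)
        hi[a] = slice(1, None)
        l1, l2 = labels[tuple(lo)], labels[tuple(hi)]
        f = ((l1 == 2) & (l2 > 0) & (l2 != 2)) | ((l2 == 2) & (l1 > 0) & (l1 != 2))
        faces.append(f)
    return faces


def apply_interface(model: WedgeModel, labels=None, hole_fraction: float = 0.05,
                    seed: int = 0) -> WedgeModel:
    """Insert a non-conducting interface with discrete holes at the bundle
    border.

    Inter-node conductances crossing the border are zeroed except for a
    reproducible pseudo-random subset of faces (fraction ``hole_fraction``)
    left intact -- the bundle is then excited at discrete points rather
    than across a plane.  ``hole_fraction = 1`` is a no-op.
    """
    if not (0.0 <= hole_fraction <= 1.0):
        raise ValueError("hole_fraction must be in [0, 1]")
    if labels is None:
        labels = model.labels
    if labels is None:
        raise ValueError("interface placement needs a label volume (bundle label 2)")
    faces = _interface_faces(labels)
    rng = substream(seed, "epsim.interface")
    keep = []
    for f in faces:
        k = np.ones(f.shape, dtype=float)
        n_iface = int(f.sum())
        if n_iface and hole_fraction < 1.0:
            holes = rng.random(n_iface) < hole_fraction
            vals = np.zeros(n_iface)
            vals[holes] = 1.0
            k[f] = vals
        keep.append(k)
    return replace(model, face_keep=tuple(keep), labels=np.asarray(labels))


@dataclass
class EPResult:
    """Output of one monodomain run."""

    lat: np.ndarray               # ms, NaN where never activated
    activated: np.ndarray         # bool per node
    tissue: np.ndarray
    times: np.ndarray             # snapshot times (ms)
    snapshots: np.ndarray         # (nt, nx, ny, nz) float32, dimensionless v
    dt: float
    dx: float
    stability_bound: float
    stimulus: dict
    flags: dict = field(default_factory=dict)


def _axis_slices(a):
    lo = [slice(None)] * 3
    hi = [slice(None)] * 3
    lo[a] = slice(None, -1)
    hi[a] = slice(1, None)
    return tuple(lo), tuple(hi)


class _DiffusionOperator:
    """Conservative face-flux discretisation of div(G grad v).

    Diagonal terms use harmonic-mean face conductances; cross terms use
    face-averaged G_ab times centred differences.  Faces to non-tissue
    nodes and domain boundary faces carry zero flux (no-flux condition);
    ``face_keep`` multipliers implement the holed interface.
    """

    def __init__(self, model: WedgeModel):
        G = model.conductivity_tensors()
        self.dx = model.dx
        self.tissue = model.tissue
        self.G = G
        self.coef = []
        self.Mface = []
        for a in range(3):
            lo, hi = _axis_slices(a)
            g1, g2 = G[lo + (a, a)], G[hi + (a, a)]
            with np.errstate(divide="ignore", invalid="ignore"):
                H = np.where(g1 + g2 > 0, 2.0 * g1 * g2 / (g1 + g2), 0.0)
            M = (model.tissue[lo] & model.tissue[hi]).astype(float)
            if model.face_keep is not None:
                M = M * model.face_keep[a]
            self.coef.append(H * M)
            self.Mface.append(M)

    def __call__(self, v):
        dx = self.dx
        grads = np.gradient(v, dx)
        out = np.zeros_like(v)
        for a in range(3):
            lo, hi = _axis_slices(a)
            cross = np.zeros_like(v)
            for b in range(3):
                if b != a:
                    cross += self.G[..., a, b] * grads[b]
            flux = self.coef[a] * (v[hi] - v[lo]) / dx
            flux += 0.5 * (cross[lo] + cross[hi]) * self.Mface[a]
            pad = [slice(None)] * 3
            pad[a] = slice(None, -1)
            out[tuple(pad)] += flux / dx
            pad[a] = slice(1, None)
            out[tuple(pad)] -= flux / dx
        return out


def _stimulus_mask(model: WedgeModel, stimulus: dict) -> np.ndarray:
    face = stimulus.get("face", "top")
    if face not in _FACES:
        raise ValueError(f"unknown stimulus face {face!r}")
    axis, side = _FACES[face]
    depth = int(stimulus.get("depth_voxels", 2))
    mode = stimulus.get("mode", "patch")
    tissue = model.tissue
    idx = np.nonzero(np.any(tissue, axis=tuple(a for a in range(3) if a != axis)))[0]
    j = idx[-1] if side else idx[0]
    sl = [slice(None)] * 3
    sl[axis] = (slice(j - depth + 1, j + 1) if side else slice(j, j + depth))
    m = np.zeros(model.shape, dtype=bool)
    m[tuple(sl)] = True
    m &= tissue
    if mode == "patch":
        radius = float(stimulus.get("radius_mm", 1.5))
        coords = np.indices(model.shape).astype(float) * model.dx
        centre = [0.5 * (np.nonzero(np.any(tissue, axis=tuple(
            b for b in range(3) if b != a)))[0][[0, -1]].sum()) * model.dx
            for a in range(3)]
        inplane = sum(
            (coords[a] - centre[a]) ** 2 for a in range(3) if a != axis
        )
        m &= inplane <= radius ** 2
    return m


def run_monodomain(
    model: WedgeModel,
    stimulus: dict,
    t_end: float = 200.0,
    lat_threshold_mv: float = -20.0,
    snapshot_stride_ms: float = 0.5,
    early_stop: bool = True,
) -> EPResult:
    """Explicit operator-split monodomain integration.

    The stimulus is a dict: ``face`` (left/right/front/back/bottom/top),
    ``mode`` ("patch" with ``radius_mm``, or "plane"), ``amplitude``
    (dimensionless 1/ms), ``duration_ms``.  LAT is the first upstroke
    crossing of ``lat_threshold_mv`` with linear sub-dt interpolation;
    nodes that never cross are NaN and flagged, not given sentinels.
    """
    dt = model.dt
    bound = model.stability_bound()
    if dt > bound:
        raise StabilityError(
            f"dt = {dt} ms exceeds the explicit stability bound {bound:.4g} ms "
            f"(dx = {model.dx} mm, sigma_max = {max(model.sigma_l, model.sigma_t)})"
        )
    mem = model.membrane
    thr = (lat_threshold_mv - mem.v_rest_mv) / mem.v_amp_mv

    op = _DiffusionOperator(model)
    tissue = model.tissue
    stim_mask = _stimulus_mask(model, stimulus)
    amp = float(stimulus.get("amplitude", 2.0))
    dur = float(stimulus.get("duration_ms", 1.0))

    v = np.zeros(model.shape)
    h = np.ones(model.shape)
    lat = np.full(model.shape, np.nan)

    n_steps = int(np.round(t_end / dt))
    snap_every = max(int(np.round(snapshot_stride_ms / dt)), 1)
    snaps, times = [], []
    last_activation = 0.0
    for s in range(n_steps):
        t = s * dt
        if s % snap_every == 0:
            snaps.append(v.astype(np.float32))
            times.append(t)
        dv = op(v)
        dv += h * v * v * (1.0 - v) / mem.tau_in - v / mem.tau_out
        if t < dur:
            dv[stim_mask] += amp
        v_old = v
        v = v + dt * dv
        v[~tissue] = 0.0
        h = h + dt * np.where(v_old < mem.v_gate,
                              (1.0 - h) / mem.tau_open, -h / mem.tau_close)
        if np.max(np.abs(v)) * mem.v_amp_mv > 500.0:
            raise StabilityError(
                f"instability detected at t = {t:.2f} ms (|Vm| > 500 mV); "
                f"dt = {dt}, bound = {bound:.4g}"
            )
        crossed = tissue & np.isnan(lat) & (v >= thr) & (v > v_old)
        if crossed.any():
            frac = (thr - v_old[crossed]) / (v[crossed] - v_old[crossed])
            lat[crossed] = t + dt * np.clip(frac, 0.0, 1.0)
            last_activation = t
        if early_stop and t > dur + 2.0:
            if not np.isnan(lat[tissue]).any() and t > last_activation + 10.0:
                n_steps = s + 1
                break

    activated = ~np.isnan(lat) & tissue
    flags = {}
    n_unactivated = int(tissue.sum() - activated.sum())
    if n_unactivated:
        flags["unactivated_nodes"] = n_unactivated
    if activated.sum() <= stim_mask.sum():
        flags["unexcited"] = True
    return EPResult(
        lat=lat, activated=activated, tissue=tissue,
        times=np.array(times), snapshots=np.array(snaps),
        dt=dt, dx=model.dx, stability_bound=bound,
        stimulus=dict(stimulus), flags=flags,
    )


def electrode_layout(model: WedgeModel, offset_mm: float = 1.5) -> tuple[dict, dict]:
    """Default labelled electrode registry on the wedge faces.

    Pairs B1-A1 (long axis), T1-T2 (transmural) and E1-E2 (circumferential)
    straddle the bundle.  The reference pairs avoid it: E2-E3 runs along
    the far circumferential face, and F1-F2 is a transmural pair at the
    basal-lateral edge -- a region activated *before* the wavefront ever
    reaches the bundle for each of the standard pacing protocols, so its
    traces are insensitive to the interface (the behaviour reported for
    non-crossing pairs).  Returns ``(electrodes, pairs)`` with positions in
    world mm (grid-corner origin).
    """
    tissue = model.tissue
    dx = model.dx
    bbox = [np.nonzero(np.any(tissue, axis=tuple(b for b in range(3) if b != a)))[0]
            for a in range(3)]
    lo = np.array([b[0] for b in bbox], dtype=float) * dx
    hi = np.array([b[-1] for b in bbox], dtype=float) * dx
    if model.labels is not None and np.any(model.labels == 2):
        c = np.argwhere(model.labels == 2).mean(axis=0) * dx
    else:
        c = 0.5 * (lo + hi)
    # basal-lateral edge position, far from the bundle in x and z
    ex = lo[0] + 0.1 * (hi[0] - lo[0])
    ez = hi[2] - 0.1 * (hi[2] - lo[2])
    electrodes = {
        "A1": np.array([c[0], c[1], lo[2] - offset_mm]),
        "B1": np.array([c[0], c[1], hi[2] + offset_mm]),
        "T1": np.array([c[0], lo[1] - offset_mm, c[2]]),
        "T2": np.array([c[0], hi[1] + offset_mm, c[2]]),
        "E1": np.array([lo[0] - offset_mm, c[1], c[2]]),
        "E2": np.array([hi[0] + offset_mm, c[1], c[2]]),
        "E3": np.array([hi[0] + offset_mm, c[1], ez]),
        "F1": np.array([ex, lo[1] - offset_mm, ez]),
        "F2": np.array([ex, hi[1] + offset_mm, ez]),
    }
    pairs = {
        "B1-A1": ("B1", "A1"),
        "T1-T2": ("T1", "T2"),
        "E1-E2": ("E1", "E2"),
        "E2-E3": ("E2", "E3"),
        "F1-F2": ("F1", "F2"),
    }
    return electrodes, pairs


def _pair_crosses_bundle(model: WedgeModel, p1, p2, n_samples: int = 200) -> bool:
    if model.labels is None:
        return False
    ts = np.linspace(0.0, 1.0, n_samples)
    pts = p1[None, :] * (1 - ts)[:, None] + p2[None, :] * ts[:, None]
    ijk = np.rint(pts / model.dx).astype(int)
    shape = np.array(model.shape)
    inside = np.all((ijk >= 0) & (ijk < shape), axis=1)
    ijk = ijk[inside]
    lab = model.labels[ijk[:, 0], ijk[:, 1], ijk[:, 2]]
    return bool(np.any(lab == 2))


def pseudo_ecg(result: EPResult, electrodes: dict, model: WedgeModel,
               pairs: dict | None = None) -> dict:
    """Unipolar and bipolar pseudo-ECG traces from stored snapshots.

    phi_e(t) = sum_nodes (G grad Vm) . grad(1/r) dV over tissue, the
    infinite-homogeneous-medium lead field; bipolar traces are differences
    of labelled pairs.  Electrodes must lie outside the tissue.
    """
    dx = model.dx
    tissue = model.tissue
    for name, pos in electrodes.items():
        ijk = np.rint(np.asarray(pos) / dx).astype(int)
        if np.all(ijk >= 0) and np.all(ijk < np.array(model.shape)):
            if tissue[tuple(ijk)]:
                raise ValueError(f"electrode {name} lies inside the tissue")
    G = model.conductivity_tensors()
    coords = np.indices(model.shape).astype(float) * dx
    tiss_idx = np.nonzero(tissue)
    leads = {}
    for name, pos in electrodes.items():
        rel = np.stack([coords[a][tiss_idx] - pos[a] for a in range(3)], axis=-1)
        r3 = np.linalg.norm(rel, axis=-1) ** 3
        leads[name] = -rel / r3[:, None]
    Gt = G[tiss_idx]
    vol = dx ** 3
    mem = model.membrane

    nt = len(result.times)
    uni = {name: np.zeros(nt) for name in electrodes}
    for it in range(nt):
        vm = result.snapshots[it].astype(float) * mem.v_amp_mv
        grads = np.gradient(vm, dx)
        gv = np.stack([g[tiss_idx] for g in grads], axis=-1)
        flow = np.einsum("nij,nj->ni", Gt, gv)
        for name in electrodes:
            uni[name][it] = np.sum(flow * leads[name]) * vol
    out = {"times": result.times.copy(), "unipolar": uni, "bipolar": {},
           "p2p": {}, "crosses_bundle": {}}
    if pairs:
        for label, (a, b) in pairs.items():
            trace = uni[a] - uni[b]
            out["bipolar"][label] = trace
            out["p2p"][label] = float(trace.max() - trace.min())
            out["crosses_bundle"][label] = _pair_crosses_bundle(
                model, np.asarray(electrodes[a]), np.asarray(electrodes[b])
            )
    for name in electrodes:
        out["p2p"].setdefault(name, float(uni[name].max() - uni[name].min()))
    return out


def planar_cv(
    sigma: float,
    length_mm: float = 8.0,
    dx: float = 0.05,
    dt: float = 0.002,
    membrane: MembraneParams | None = None,
    width_nodes: int = 3,
) -> float:
    """Conduction velocity (mm/ms) of a planar wave along a quasi-1D bar.

    The bar has isotropic effective diffusivity ``sigma`` along its axis
    (a uniform-fiber bar paced along or across the fibers reduces to this
    with sigma = sigma_L or sigma_T).  CV is measured between the 30% and
    70% stations to avoid stimulus and boundary transients.
    """
    n = int(np.round(length_mm / dx))
    shape = (n, width_nodes, width_nodes)
    fibers = np.zeros(shape + (3,))
    fibers[..., 0] = 1.0
    model = WedgeModel(fibers=fibers, dx=dx, sigma_l=sigma, sigma_t=sigma,
                       dt=dt, membrane=membrane or MembraneParams())
    res = run_monodomain(
        model,
        {"face": "left", "mode": "plane", "amplitude": 3.0,
         "duration_ms": 1.0, "depth_voxels": 3},
        t_end=max(4.0 * length_mm / np.sqrt(sigma), 60.0),
    )
    mid = width_nodes // 2
    lat_line = res.lat[:, mid, mid]
    i1, i2 = int(0.3 * n), int(0.7 * n)
    if np.isnan(lat_line[i1]) or np.isnan(lat_line[i2]):
        raise RuntimeError("wave did not traverse the bar; check parameters")
    return float((i2 - i1) * dx / (lat_line[i2] - lat_line[i1]))


#: Bipolar pair perpendicular to each pacing wavefront (the informative
#: pair for that protocol; pairs parallel to a symmetric wavefront are
#: degenerate by mirror symmetry).
ALIGNED_PAIRS = {
    "top": "B1-A1", "bottom": "B1-A1",
    "left": "E1-E2", "right": "E1-E2",
    "front": "T1-T2", "back": "T1-T2",
}


def measured_fibers(phantom, snr: float = 50.0, seed: int = 0) -> np.ndarray:
    """Fiber field "as measured": DTI v1 of the simulated acquisition.

    Simulates the 6+1 diffusion acquisition of the phantom at the given
    Rician SNR, fits the tensor, and returns the principal eigenvector per
    tissue voxel.  This is the experimental-style field for the EP study:
    it carries the genuine angular dispersion of a DTI measurement rather
    than the clean generative orientations.
    """
    from . import dti as _dti
    from . import phantoms as _ph

    scheme = _ph.default_scheme(snr=snr, seed=seed)
    dwi = _ph.simulate_dwi(phantom, scheme=scheme)
    tf = _dti.fit_tensor(dwi, mask=phantom.myocardium)
    v1 = _dti.tensor_metrics(tf)["v1"]
    v1 = np.where(phantom.myocardium[..., None], v1, 0.0)
    return v1


def compare_configurations(
    phantom,
    pacing_faces=("top", "left", "front"),
    sigma_l: float = 0.12,
    sigma_t: float = 0.03,
    hole_fraction: float = 0.05,
    seed: int = 0,
    dt: float = 0.02,
    t_end: float = 250.0,
    stimulus_radius_mm: float = 1.5,
    snapshot_stride_ms: float = 0.5,
    measured_snr: float | None = 50.0,
    experimental_fibers: np.ndarray | None = None,
) -> dict:
    """The wedge study: rule-based vs measured-style vs measured+interface.

    For each pacing face, three monodomain runs share the grid and
    stimulus: (1) rule-based transmural helix ramp, (2) the experimental
    configuration -- by default the DTI-*measured* principal eigenvector
    field of the phantom at ``measured_snr`` (the bundle plus realistic
    measurement dispersion), or ``experimental_fibers`` /
    ``phantom.fibers`` if given -- and (3) the same field plus the
    non-conducting holed interface at the bundle border.  The report holds
    LAT maps, Delta-LAT (2-1, 3-1) statistics over commonly activated
    nodes, bundle-interior LAT means, and pseudo-ECG peak-to-peak
    amplitudes per labelled bipolar pair (the pair perpendicular to each
    wavefront is flagged), with all seeds and parameters echoed.
    """
    dx = float(phantom.spacing[0])
    if not np.allclose(phantom.spacing, dx):
        raise ValueError("EP grid requires isotropic phantom spacing")
    tissue = phantom.myocardium
    labels = phantom.labels

    if experimental_fibers is None:
        if measured_snr is None or not np.isfinite(measured_snr):
            experimental_fibers = phantom.fibers.copy()
        else:
            experimental_fibers = measured_fibers(phantom, snr=measured_snr,
                                                  seed=seed)

    base = dict(dx=dx, sigma_l=sigma_l, sigma_t=sigma_t, dt=dt)
    m_rule = WedgeModel(
        fibers=rule_based_fibers(tissue.shape, tissue=tissue),
        tissue=tissue, labels=labels, **base)
    m_exp = WedgeModel(fibers=np.asarray(experimental_fibers, dtype=float),
                       tissue=tissue, labels=labels, **base)
    m_iface = apply_interface(m_exp, labels=labels,
                              hole_fraction=hole_fraction, seed=seed)
    models = {"rule_based": m_rule, "experimental": m_exp,
              "experimental_interface": m_iface}

    electrodes, pairs = electrode_layout(m_exp)
    bundle = labels == 2
    report = {
        "params": {
            "dx": dx, "dt": dt, "sigma_l": sigma_l, "sigma_t": sigma_t,
            "hole_fraction": hole_fraction, "seed": seed,
            "stimulus_radius_mm": stimulus_radius_mm, "t_end": t_end,
            "measured_snr": measured_snr,
        },
        "electrodes": {k: v.tolist() for k, v in electrodes.items()},
        "faces": {},
    }
    for face in pacing_faces:
        stim = {"face": face, "mode": "patch", "radius_mm": stimulus_radius_mm,
                "amplitude": 2.0, "duration_ms": 1.0}
        runs, ecgs = {}, {}
        for name, model in models.items():
            res = run_monodomain(model, stim, t_end=t_end,
                                 snapshot_stride_ms=snapshot_stride_ms)
            runs[name] = res
            ecgs[name] = pseudo_ecg(res, electrodes, model, pairs)
        lat1 = runs["rule_based"].lat
        entry = {"lat": {k: r.lat for k, r in runs.items()},
                 "flags": {k: r.flags for k, r in runs.items()},
                 "aligned_pair": ALIGNED_PAIRS.get(face),
                 "delta_lat": {}, "ecg_p2p": {}, "amp_change_pct_3v2": {},
                 "crosses_bundle": ecgs["experimental"]["crosses_bundle"]}
        for key, name in (("2-1", "experimental"),
                          ("3-1", "experimental_interface")):
            both = runs[name].activated & runs["rule_based"].activated
            d = runs[name].lat[both] - lat1[both]
            entry["delta_lat"][key] = {
                "mean_ms": float(d.mean()), "sd_ms": float(d.std()),
                "n": int(both.sum()),
            }
        for name in models:
            entry["ecg_p2p"][name] = dict(ecgs[name]["p2p"])
        for label in pairs:
            a2 = ecgs["experimental"]["p2p"][label]
            a3 = ecgs["experimental_interface"]["p2p"][label]
            entry["amp_change_pct_3v2"][label] = float(
                100.0 * abs(a3 - a2) / max(abs(a2), 1e-12))
        if bundle.any():
            in2 = float(np.nanmean(runs["experimental"].lat[bundle]))
            in3 = float(np.nanmean(runs["experimental_interface"].lat[bundle]))
        else:
            in2 = in3 = float("nan")
        entry["bundle_lat"] = {
            "experimental_mean_ms": in2,
            "experimental_interface_mean_ms": in3,
            "n_bundle": int(bundle.sum()),
        }
        report["faces"][face] = entry
    return report
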