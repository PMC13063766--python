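"""Ground-truth MSI phantoms emulating amyloid plaque pathology.

A phantom is a rectangular tissue field (default 150 x 150 pixels at 20 um)
carrying non-overlapping elliptical A-beta plaques and thin elongated
tau-tangle blobs. Each plaque draws a peptide composition from a Dirichlet
distribution centred on its group's truncation-category weights; each pixel's
profile spectrum is rendered as the sum of isotope-envelope Gaussians (at a
fixed instrument peak width), a diffuse parenchyma component with the same
group composition, an exponentially decaying chemical baseline, and white
noise, all scaled by a per-pixel total-ion-current multiplier. Tangles are
tau pathology and contribute no A-beta signal: they exist only in the deposit
masks used for fluorescence-style morphometry.

The default group specifications encode the study conditions this package is
validated against: sAD-profile tissue with 23.5 % C-terminally and 45.9 %
N-terminally truncated A-beta signal and DS-profile tissue with 11.1 % and
75.2 % respectively, a five-fold DS/sAD plaque-area ratio and a two-fold
tangle-area ratio, and N-truncated terminal splits favouring x-40 in sAD and
x-42 in DS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import MSIDataset
from .masslist import PeptideVariant, make_variant, variant_name

__all__ = [
    "GroupSpec",
    "PhantomConfig",
    "GroundTruth",
    "PlaqueTruth",
    "PlacementError",
    "build_variant_weights",
    "sad_group",
    "ds_group",
    "control_group",
    "generate_phantom",
    "generate_layout",
    "generate_two_group_cohort",
    "iter_two_group_cohort",
    "render_deposit_masks",
    "SAD_CATEGORY_WEIGHTS",
    "DS_CATEGORY_WEIGHTS",
]


class PlacementError(RuntimeError):
    """Requested deposits cannot be placed without overlap; use a larger grid."""


# Truncation-category intensity shares (full-length, N-, C-, bi-truncated).
SAD_CATEGORY_WEIGHTS = {
    "full_length": 0.241,
    "N_truncated": 0.459,
    "C_truncated": 0.235,
    "bi_truncated": 0.065,
}
DS_CATEGORY_WEIGHTS = {
    "full_length": 0.137,
    "N_truncated": 0.752,
    "C_truncated": 0.111,
    "bi_truncated": 0.0,
}

# Within-category species repertoires (relative weights, normalised later).
# sAD carries broader C-terminal and unique bi-terminal truncations; DS is
# dominated by N-truncated and pyroglutamate species.
_SAD_WITHIN = {
    "full_length": {"Abeta1-42": 0.6, "Abeta1-40": 0.4},
    "C_truncated": {"Abeta1-38": 0.35, "Abeta1-39": 0.30, "Abeta1-37": 0.20, "Abeta1-36": 0.15},
    "N_truncated_40": {
        "Abeta4-40": 0.30, "Abeta2-40": 0.20, "AbetapE3-40": 0.20,
        "Abeta5-40": 0.10, "Abeta7-40": 0.07, "Abeta8-40": 0.07, "Abeta9-40": 0.06,
    },
    "N_truncated_42": {"Abeta10-42": 1.0},
    "bi_truncated": {"Abeta2-39": 0.40, "Abeta2-37": 0.35, "Abeta9-38": 0.25},
}
_DS_WITHIN = {
    "full_length": {"Abeta1-42": 0.65, "Abeta1-40": 0.35},
    "C_truncated": {"Abeta1-38": 0.6, "Abeta1-39": 0.4},
    "N_truncated_40": {
        "AbetapE3-40": 0.25, "Abeta3-40": 0.20, "Abeta4-40": 0.20,
        "Abeta2-40": 0.15, "AbetapE11-40": 0.10, "Abeta8-40": 0.05, "Abeta9-40": 0.05,
    },
    "N_truncated_42": {
        "AbetapE3-42": 0.30, "Abeta4-42": 0.25, "Abeta2-42": 0.20,
        "Abeta8-42": 0.10, "AbetapE11-42": 0.10, "Abeta10-42": 0.05,
    },
    "bi_truncated": {},
}


def build_variant_weights(
    category_weights: dict[str, float],
    within_category: dict[str, dict[str, float]],
    terminal_split_40_42: tuple[float, float],
) -> dict[str, float]:
    """Combine category weights, within-category weights and the N-truncated
    terminal split into one normalised per-species weight vector."""
    total_cat = sum(category_weights.values())
    if abs(total_cat - 1.0) > 1e-9:
        raise ValueError("category weights must sum to 1")
    s40, s42 = terminal_split_40_42
    if abs(s40 + s42 - 1.0) > 1e-9:
        raise ValueError("terminal split must sum to 1")
    weights: dict[str, float] = {}

    def add(block: dict[str, float], mass: float) -> None:
        total = sum(block.values())
        if mass > 0 and total <= 0:
            raise ValueError("positive category weight with empty repertoire")
        for name, w in block.items():
            weights[name] = weights.get(name, 0.0) + mass * w / total

    add(within_category.get("full_length", {}), category_weights["full_length"])
    add(within_category.get("C_truncated", {}), category_weights["C_truncated"])
    n_mass = category_weights["N_truncated"]
    add(within_category.get("N_truncated_40", {}), n_mass * s40)
    add(within_category.get("N_truncated_42", {}), n_mass * s42)
    add(within_category.get("bi_truncated", {}), category_weights["bi_truncated"])
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


@dataclass(frozen=True)
class GroupSpec:
    """Pathology parameters of one diagnostic group."""

    name: str
    n_plaques: int = 150
    n_tangles: int = 100
    plaque_area_um2: float = 1600.0
    plaque_area_sigma: float = 0.4   # lognormal shape (log-scale sd)
    tangle_area_um2: float = 1200.0
    tangle_area_sigma: float = 0.4
    variant_weights: dict[str, float] = field(default_factory=dict)
    plaque_enrichment: float = 30.0
    composition_dirichlet_concentration: float = 50.0
    subject_dirichlet_concentration: float = 2000.0

    def __post_init__(self) -> None:
        if self.n_plaques < 0 or self.n_tangles < 0:
            raise ValueError("deposit counts must be >= 0")
        if self.variant_weights:
            total = sum(self.variant_weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("variant weights must sum to 1")


def sad_group(**overrides) -> GroupSpec:
    """sAD-profile group: small plaques, x-40-dominated N-truncation,
    broader C- and bi-terminal truncation diversity."""
    spec = GroupSpec(
        name="sAD",
        variant_weights=build_variant_weights(SAD_CATEGORY_WEIGHTS, _SAD_WITHIN, (0.85, 0.15)),
    )
    return replace(spec, **overrides)


def ds_group(**overrides) -> GroupSpec:
    """DS-profile group: five-fold larger plaques, two-fold larger tangles,
    N-truncation-dominated composition ending mostly at residue 42."""
    spec = GroupSpec(
        name="DS",
        plaque_area_um2=8000.0,
        tangle_area_um2=2400.0,
        variant_weights=build_variant_weights(DS_CATEGORY_WEIGHTS, _DS_WITHIN, (0.35, 0.65)),
    )
    return replace(spec, **overrides)


def control_group(**overrides) -> GroupSpec:
    """Non-demented control tissue: no plaques, no tangles, no A-beta signal."""
    spec = GroupSpec(name="Ctrl", n_plaques=0, n_tangles=0, variant_weights={})
    return replace(spec, **overrides)


@dataclass(frozen=True)
class PhantomConfig:
    """Acquisition and tissue-field parameters of one phantom section."""

    group: GroupSpec
    grid: tuple[int, int] = (150, 150)     # (ny, nx) pixels
    pixel_size_um: float = 20.0
    mz_start: float = 2500.0
    mz_stop: float = 5000.0
    mz_step: float = 0.1
    resolving_power: float = 6000.0
    noise_sd: float = 1.0
    baseline_amplitude: float = 30.0
    baseline_decay: float = 800.0          # Da
    parenchyma_amplitude: float = 30.0
    tic_sigma: float = 0.25                # lognormal sd of per-pixel TIC
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolving_power <= 0:
            raise ValueError("resolving power must be positive")
        if self.mz_step <= 0 or self.mz_stop <= self.mz_start:
            raise ValueError("invalid m/z axis")

    @property
    def peak_fwhm(self) -> float:
        """Constant peak width: FWHM at the window centre m/z."""
        return 0.5 * (self.mz_start + self.mz_stop) / self.resolving_power


@dataclass
class EllipseParams:
    center_um: tuple[float, float]
    semi_axes_um: tuple[float, float]
    angle_rad: float


@dataclass
class PlaqueTruth:
    plaque_id: int
    kind: str                       # "plaque" or "tangle"
    ellipse: EllipseParams
    pixel_rows: np.ndarray          # dataset row indices (empty for tangles w/o signal)
    area_um2: float                 # rasterised area at the MSI grid
    weights: dict[str, float]       # generating composition (plaques only)


@dataclass
class GroundTruth:
    group: str
    subject: str
    plaque_mask: np.ndarray
    tangle_mask: np.ndarray
    plaques: list[PlaqueTruth]
    tangles: list[PlaqueTruth]
    tic_multipliers: np.ndarray
    subject_weights: dict[str, float]
    pixel_size_um: float

    def mean_area_um2(self, kind: str = "plaque") -> float:
        items = self.plaques if kind == "plaque" else self.tangles
        return float(np.mean([p.area_um2 for p in items])) if items else np.nan


def _rasterize_ellipse(e: EllipseParams, grid: tuple[int, int], pixel_size: float):
    """Pixel-centre-in-ellipse rasterisation; returns (ys, xs) index arrays."""
    ny, nx = grid
    cx, cy = e.center_um
    a, b = e.semi_axes_um
    r = max(a, b)
    x0 = max(0, int((cx - r) / pixel_size) - 1)
    x1 = min(nx - 1, int((cx + r) / pixel_size) + 1)
    y0 = max(0, int((cy - r) / pixel_size) - 1)
    y1 = min(ny - 1, int((cy + r) / pixel_size) + 1)
    if x1 < x0 or y1 < y0:
        return np.empty(0, int), np.empty(0, int)
    xs = (np.arange(x0, x1 + 1) + 0.5) * pixel_size
    ys = (np.arange(y0, y1 + 1) + 0.5) * pixel_size
    gx, gy = np.meshgrid(xs - cx, ys - cy)
    c, s = np.cos(e.angle_rad), np.sin(e.angle_rad)
    u = gx * c + gy * s
    v = -gx * s + gy * c
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    iy, ix = np.nonzero(inside)
    if len(iy) == 0:
        # guarantee at least the centre pixel for very small deposits
        py, px = int(cy / pixel_size), int(cx / pixel_size)
        if 0 <= py < ny and 0 <= px < nx:
            return np.array([py]), np.array([px])
        return np.empty(0, int), np.empty(0, int)
    return iy + y0, ix + x0


def _place_deposits(
    rng: np.random.Generator,
    n: int,
    mean_area: float,
    sigma: float,
    aspect_range: tuple[float, float],
    grid: tuple[int, int],
    pixel_size: float,
    occupied: np.ndarray,
    kind: str,
    max_tries: int = 500,
) -> list[tuple[EllipseParams, np.ndarray, np.ndarray]]:
    """Rejection-sample non-overlapping ellipses (1-pixel separation ring).

    Areas are lognormal with the requested mean (log-mean shifted by
    -sigma^2/2 so the arithmetic mean equals ``mean_area``).
    """
    ny, nx = grid
    out = []
    mu = np.log(mean_area) - sigma**2 / 2
    for _ in range(n):
        placed = False
        for _ in range(max_tries):
            area = float(rng.lognormal(mu, sigma))
            aspect = float(rng.uniform(*aspect_range))
            a = np.sqrt(area * aspect / np.pi)
            b = np.sqrt(area / (aspect * np.pi))
            angle = float(rng.uniform(0, np.pi))
            cx = float(rng.uniform(a, nx * pixel_size - a))
            cy = float(rng.uniform(a, ny * pixel_size - a))
            e = EllipseParams((cx, cy), (a, b), angle)
            iy, ix = _rasterize_ellipse(e, grid, pixel_size)
            if len(iy) == 0:
                continue
            # check a 1-pixel ring around the candidate for occupancy
            ring_y = np.clip(iy[:, None] + np.array([-1, 0, 1]), 0, ny - 1)
            ring_x = np.clip(ix[:, None] + np.array([-1, 0, 1]), 0, nx - 1)
            hit = False
            for dy in range(3):
                for dx in range(3):
                    if occupied[ring_y[:, dy], ring_x[:, dx]].any():
                        hit = True
                        break
                if hit:
                    break
            if hit:
                continue
            occupied[iy, ix] = True
            out.append((e, iy, ix))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place {kind} {len(out) + 1}/{n} without overlap; "
                "use a larger grid or fewer/smaller deposits"
            )
    return out


def _render_template(
    mz: np.ndarray,
    weights: dict[str, float],
    variants: dict[str, PeptideVariant],
    fwhm: float,
    min_p: float = 1e-4,
) -> np.ndarray:
    """Unit-amplitude spectrum of a composition: weighted envelope Gaussians.

    Peaks are rendered with unit apex per unit isotopologue probability, so
    the summed apex intensity of a species is proportional to its weight.
    """
    sd = fwhm / 2.354820045
    tmpl = np.zeros(len(mz))
    step = mz[1] - mz[0]
    half = int(np.ceil(4 * sd / step))
    for name, w in weights.items():
        if w <= 0:
            continue
        v = variants[name]
        for p, pos in zip(v.envelope.probabilities, v.envelope.mz_positions):
            if p < min_p:
                continue
            j = int(round((pos - mz[0]) / step))
            lo, hi = max(0, j - half), min(len(mz), j + half + 1)
            if lo >= hi:
                continue
            tmpl[lo:hi] += w * p * np.exp(-0.5 * ((mz[lo:hi] - pos) / sd) ** 2)
    return tmpl


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet draw that tolerates zero concentrations (mass stays zero)."""
    draw = np.where(alpha > 0, rng.gamma(np.maximum(alpha, 1e-12)), 0.0)
    total = draw.sum()
    if total <= 0:
        return alpha / alpha.sum() if alpha.sum() > 0 else draw
    return draw / total


def _variant_cache(names) -> dict[str, PeptideVariant]:
    cache = {}
    for name in names:
        body = name.removeprefix("Abeta")
        pyro = body.startswith("pE")
        if pyro:
            body = body[2:]
        start, end = (int(x) for x in body.split("-"))
        cache[name] = make_variant(start, end, pyro)
    return cache


def generate_layout(
    cfg: PhantomConfig, subject: str | None = None,
    subject_weights: dict[str, float] | None = None,
) -> GroundTruth:
    """Ground truth only (deposit layout and compositions), no spectra.

    Identical to the ground truth of :func:`generate_phantom` under the same
    configuration and seed; used when only morphometry is studied.
    """
    _, truth = generate_phantom(cfg, subject, subject_weights, render=False)
    return truth


def generate_phantom(
    cfg: PhantomConfig, subject: str | None = None,
    subject_weights: dict[str, float] | None = None, render: bool = True
) -> tuple[MSIDataset | None, GroundTruth]:
    """Render one phantom tissue section with full ground truth.

    Deterministic given ``cfg.seed``. ``subject_weights`` overrides the
    subject-level composition (used by the cohort generator to add
    between-subject variability around the group composition). With
    ``render=False`` the spectra are skipped (the returned dataset is None)
    but the ground truth — including the random draws — is unchanged.
    """
    rng = np.random.default_rng(cfg.seed)
    ny, nx = cfg.grid
    group = cfg.group
    mz = np.arange(cfg.mz_start, cfg.mz_stop + cfg.mz_step / 2, cfg.mz_step)
    n_px = ny * nx

    names = sorted(group.variant_weights)
    variants = _variant_cache(names)
    base_w = np.array([group.variant_weights[n] for n in names])
    if subject_weights is None:
        if len(names):
            sw = _dirichlet(rng, group.subject_dirichlet_concentration * base_w)
            subject_weights = dict(zip(names, sw))
        else:
            subject_weights = {}
    sw_vec = np.array([subject_weights[n] for n in names]) if names else np.empty(0)

    # layout
    occupied = np.zeros((ny, nx), dtype=bool)
    plaque_geom = _place_deposits(
        rng, group.n_plaques, group.plaque_area_um2, group.plaque_area_sigma,
        (1.0, 2.0), cfg.grid, cfg.pixel_size_um, occupied, "plaque",
    )
    tangle_geom = _place_deposits(
        rng, group.n_tangles, group.tangle_area_um2, group.tangle_area_sigma,
        (4.0, 8.0), cfg.grid, cfg.pixel_size_um, occupied, "tangle",
    )

    coords = np.column_stack(
        [np.tile(np.arange(1, nx + 1), ny), np.repeat(np.arange(1, ny + 1), nx)]
    )
    row_index = lambda iy, ix: iy * nx + ix

    # spectra
    Y = None
    if render:
        Y = np.empty((n_px, len(mz)), dtype=np.float32)
        baseline = cfg.baseline_amplitude * np.exp(-(mz - cfg.mz_start) / cfg.baseline_decay)
        parenchyma = (
            _render_template(mz, subject_weights, variants, cfg.peak_fwhm)
            if names
            else np.zeros(len(mz))
        )
        Y[:] = (baseline + cfg.parenchyma_amplitude * parenchyma).astype(np.float32)

    plaque_mask = np.zeros((ny, nx), dtype=bool)
    tangle_mask = np.zeros((ny, nx), dtype=bool)
    plaques: list[PlaqueTruth] = []
    tangles: list[PlaqueTruth] = []
    px_area = cfg.pixel_size_um**2

    for i, (e, iy, ix) in enumerate(plaque_geom):
        alpha = group.composition_dirichlet_concentration * sw_vec
        w = _dirichlet(rng, alpha)
        wdict = dict(zip(names, w))
        rows = row_index(iy, ix)
        if render:
            tmpl = _render_template(mz, wdict, variants, cfg.peak_fwhm)
            Y[rows] += (
                cfg.parenchyma_amplitude * group.plaque_enrichment * tmpl
            ).astype(np.float32)
        plaque_mask[iy, ix] = True
        plaques.append(
            PlaqueTruth(
                plaque_id=i + 1, kind="plaque", ellipse=e, pixel_rows=rows,
                area_um2=len(iy) * px_area, weights=wdict,
            )
        )
    for i, (e, iy, ix) in enumerate(tangle_geom):
        tangle_mask[iy, ix] = True
        tangles.append(
            PlaqueTruth(
                plaque_id=i + 1, kind="tangle", ellipse=e,
                pixel_rows=row_index(iy, ix), area_um2=len(iy) * px_area, weights={},
            )
        )

    tic = rng.lognormal(0.0, cfg.tic_sigma, size=n_px).astype(np.float32)
    dataset = None
    if render:
        Y *= tic[:, None]
        if cfg.noise_sd > 0:
            # render noise in float32 blocks to bound peak memory on large grids
            block = max(1, (1 << 24) // len(mz))
            for lo in range(0, n_px, block):
                hi = min(n_px, lo + block)
                noise = rng.standard_normal((hi - lo, len(mz)), dtype=np.float32)
                noise *= np.float32(cfg.noise_sd)
                Y[lo:hi] += noise
        np.maximum(Y, 0.0, out=Y)
        dataset = MSIDataset(
            mz=mz, intensities=Y, coords=coords, pixel_size_um=cfg.pixel_size_um,
            metadata={"group": group.name, "subject": subject or group.name, "seed": cfg.seed},
        )
    truth = GroundTruth(
        group=group.name, subject=subject or group.name,
        plaque_mask=plaque_mask, tangle_mask=tangle_mask,
        plaques=plaques, tangles=tangles, tic_multipliers=tic,
        subject_weights=subject_weights, pixel_size_um=cfg.pixel_size_um,
    )
    return dataset, truth


def render_deposit_masks(
    truth: GroundTruth, pixel_size_um: float, grid_um: tuple[float, float]
):
    """Re-rasterise the true deposit ellipses at an arbitrary pixel size.

    Emulates the higher-resolution fluorescence modality: the same physical
    deposits, sampled on a finer raster than the MSI grid.
    """
    from .registration import DepositMask

    ny = int(round(grid_um[0] / pixel_size_um))
    nx = int(round(grid_um[1] / pixel_size_um))
    out = {}
    for kind, items in (("plaque", truth.plaques), ("tangle", truth.tangles)):
        mask = np.zeros((ny, nx), dtype=bool)
        for p in items:
            iy, ix = _rasterize_ellipse(p.ellipse, (ny, nx), pixel_size_um)
            mask[iy, ix] = True
        out[kind] = DepositMask(mask=mask, pixel_size_um=pixel_size_um, kind=kind)
    return out["plaque"], out["tangle"]


def iter_two_group_cohort(
    cfg_a: PhantomConfig,
    cfg_b: PhantomConfig,
    n_subjects_per_group: int = 3,
    seed: int = 0,
    poisson_counts: bool = True,
    render: bool = True,
):
    """Lazily generate a two-group cohort, one subject phantom at a time.

    Each subject gets an independent seed (spawned from ``seed``), a
    composition drawn around the group composition at the group's
    subject-level Dirichlet concentration, and (optionally) Poisson-jittered
    deposit counts. Lazy generation keeps at most one full datacube in
    memory, which matters at realistic grid sizes.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_subjects_per_group)
    idx = 0
    for cfg in (cfg_a, cfg_b):
        for s in range(n_subjects_per_group):
            child_seed = int(children[idx].generate_state(1)[0] % (2**31 - 1))
            idx += 1
            rng = np.random.default_rng(child_seed)
            group = cfg.group
            if poisson_counts and group.n_plaques > 0:
                n_plaques = max(1, int(rng.poisson(group.n_plaques)))
                n_tangles = int(rng.poisson(group.n_tangles))
            else:
                n_plaques, n_tangles = group.n_plaques, group.n_tangles
            names = sorted(group.variant_weights)
            if names:
                base = np.array([group.variant_weights[n] for n in names])
                sw = dict(zip(names, _dirichlet(rng, group.subject_dirichlet_concentration * base)))
            else:
                sw = {}
            sub_cfg = replace(
                cfg,
                group=replace(group, n_plaques=n_plaques, n_tangles=n_tangles),
                seed=child_seed,
            )
            subject = f"{group.name}{s + 1}"
            yield generate_phantom(sub_cfg, subject=subject, subject_weights=sw, render=render)


def generate_two_group_cohort(
    cfg_a: PhantomConfig,
    cfg_b: PhantomConfig,
    n_subjects_per_group: int = 3,
    seed: int = 0,
    poisson_counts: bool = True,
    render: bool = True,
) -> list[tuple[MSIDataset | None, GroundTruth]]:
    """Materialised form of :func:`iter_two_group_cohort` (small grids)."""
    return list(
        iter_two_group_cohort(
            cfg_a, cfg_b, n_subjects_per_group, seed, poisson_counts, render
        )
    )
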