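"""Ground-truth-labelled synthetic imaging-flow-cytometry events.

Environmental biofilm swabs are not distributable, so this module generates
event imagery with the statistical structure the downstream analysis
assumes: a mixture of singlets, small aggregates (2–3 cells), large
aggregates (>3 cells), fluorophore-free debris and out-of-focus events,
with per-cell physiological states (active / mid-active / dead) driving
the green (redox dye, Ch02) and red (propidium iodide, Ch05) intensities.

Every generated event carries an :class:`EventTruth` record so that
filters, gates and classifiers can be validated against known labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .events import CHANNELS, MAX_COUNTS, EventImageSet

EVENT_CLASSES = ("singlet", "small_aggregate", "large_aggregate", "debris")
CELL_STATES = ("active", "mid_active", "dead")

_MANIFEST_COLUMNS = [
    "event_id",
    "file",
    "pixel_scale_um",
    "event_class",
    "n_cells",
    "states",
    "blur_sigma",
    "seed",
]


@dataclass(frozen=True)
class CellSpec:
    """Geometry and physiology of one cell inside an event.

    ``center`` is a 0-based (row, col) position; ``radius`` is the
    semi-major axis in pixels; ``eccentricity`` in [0, 1) elongates the
    cell into an ellipse oriented at ``orientation`` radians.
    """

    center: tuple[float, float]
    radius: float
    state: str
    eccentricity: float = 0.0
    orientation: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("cell radius must be > 0")
        if self.state not in CELL_STATES:
            raise ValueError(f"unknown cell state {self.state!r}")
        if not 0.0 <= self.eccentricity < 1.0:
            raise ValueError("eccentricity must lie in [0, 1)")

    @property
    def semi_minor(self) -> float:
        return self.radius * float(np.sqrt(1.0 - self.eccentricity**2))


@dataclass(frozen=True)
class EventSpec:
    """Full geometric description of one event prior to rendering."""

    event_class: str
    cells: tuple[CellSpec, ...]
    blur_sigma: float = 0.0
    image_size: tuple[int, int] = (64, 64)
    pixel_scale_um: float = 1.0
    # (row, col, radius) specks for debris events; cells must be empty then.
    debris_specks: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.cells)
        cls = self.event_class
        if cls not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {cls!r}")
        if cls == "singlet" and n != 1:
            raise ValueError("singlet must contain exactly 1 cell")
        if cls == "small_aggregate" and not 2 <= n <= 3:
            raise ValueError("small aggregate must contain 2-3 cells")
        if cls == "large_aggregate" and n < 4:
            raise ValueError("large aggregate must contain >= 4 cells")
        if cls == "debris" and n != 0:
            raise ValueError("debris events contain no cells")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")


@dataclass(frozen=True)
class IntensityModel:
    """Log-normal per-(channel, state) fluorescence amplitudes plus camera noise.

    ``locations``/``scales`` parameterize ``lognormal(mean=loc, sigma=scale)``
    per channel and cell state, so ``exp(loc)`` is the median amplitude in
    camera counts. The redox dye (Ch02) amplitude decreases from active to
    dead cells; propidium iodide (Ch05) lights up only membrane-compromised
    (dead) cells. Brightfield renders cells as absorbing (darker than
    background) objects and SSC as multiplicative speckle inside cells.
    """

    locations: dict[tuple[str, str], float]
    scales: dict[tuple[str, str], float]
    background: dict[str, float]
    read_noise_sigma: float = 2.0
    bf_absorbance: float = 250.0
    ssc_amplitude: float = 200.0
    ssc_speckle_sigma: float = 0.6
    debris_bf_contrast: float = 200.0
    debris_ssc_amplitude: float = 30.0

    def __post_init__(self) -> None:
        for key, s in self.scales.items():
            if s <= 0:
                raise ValueError(f"scale for {key} must be > 0")
        loc = self.locations
        if not (
            loc[("Ch02", "active")] > loc[("Ch02", "mid_active")] > loc[("Ch02", "dead")]
        ):
            raise ValueError("Ch02 amplitude must order active > mid_active > dead")
        if not (
            loc[("Ch05", "dead")] > loc[("Ch05", "active")]
            and loc[("Ch05", "dead")] > loc[("Ch05", "mid_active")]
        ):
            raise ValueError("Ch05 amplitude must be highest for dead cells")


def default_intensity_model() -> IntensityModel:
    """Default amplitudes on the 0–1023 count scale.

    Medians: Ch02 (redox green) 500 / 150 / 30 counts for active /
    mid-active / dead; Ch05 (PI red) 450 counts for dead, 15 otherwise.
    Chosen for clear but overlapping state clusters on log-intensity axes;
    the staining-positivity cut (raw max pixel > 100) then retains stained
    cells while fluorophore-free debris stays at background.
    """
    ln = np.log
    return IntensityModel(
        locations={
            ("Ch02", "active"): float(ln(500.0)),
            ("Ch02", "mid_active"): float(ln(150.0)),
            ("Ch02", "dead"): float(ln(30.0)),
            ("Ch05", "active"): float(ln(15.0)),
            ("Ch05", "mid_active"): float(ln(15.0)),
            ("Ch05", "dead"): float(ln(450.0)),
        },
        scales={
            ("Ch02", "active"): 0.25,
            ("Ch02", "mid_active"): 0.25,
            ("Ch02", "dead"): 0.30,
            ("Ch05", "active"): 0.30,
            ("Ch05", "mid_active"): 0.30,
            ("Ch05", "dead"): 0.25,
        },
        background={"Ch01": 600.0, "Ch02": 8.0, "Ch05": 8.0, "Ch06": 15.0},
    )


@dataclass(frozen=True)
class EventTruth:
    """Ground-truth record for a generated event."""

    event_id: str
    event_class: str
    n_cells: int
    states: tuple[str, ...]
    blur_sigma: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_cells != len(self.states):
            raise ValueError("n_cells must equal number of recorded states")


@dataclass(frozen=True)
class SampleConfig:
    """Study conditions for one synthetic sample.

    ``class_mix`` covers the three cellular classes and is rescaled by
    ``(1 - debris_fraction)`` so that the four-way event mixture sums to 1.
    Defaults follow the acquisition regime the pipeline targets: 5000
    events per file, 20x-magnification pixel scale, 64x64 px event crops.
    """

    n_events: int = 5000
    class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "singlet": 0.60,
            "small_aggregate": 0.25,
            "large_aggregate": 0.15,
        }
    )
    debris_fraction: float = 0.05
    state_mix: dict[str, float] = field(
        default_factory=lambda: {"active": 0.40, "mid_active": 0.30, "dead": 0.30}
    )
    out_of_focus_fraction: float = 0.10
    image_size: tuple[int, int] = (64, 64)
    pixel_scale_um: float = 1.0
    radius_range: tuple[float, float] = (3.0, 6.0)
    eccentricity_max: float = 0.3
    small_aggregate_cells: tuple[int, int] = (2, 3)
    large_aggregate_cells: tuple[int, int] = (4, 7)
    blur_in_focus: tuple[float, float] = (0.0, 0.5)
    blur_out_of_focus: tuple[float, float] = (2.0, 4.0)
    model: IntensityModel = field(default_factory=default_intensity_model)

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1 within 1e-9")
        if abs(sum(self.state_mix.values()) - 1.0) > 1e-9:
            raise ValueError("state_mix proportions must sum to 1 within 1e-9")
        if not 0.0 <= self.debris_fraction <= 1.0:
            raise ValueError("debris_fraction must lie in [0, 1]")
        if not 0.0 <= self.out_of_focus_fraction <= 1.0:
            raise ValueError("out_of_focus_fraction must lie in [0, 1]")

    @property
    def event_class_probs(self) -> np.ndarray:
        """Four-way event mixture (singlet, small, large, debris)."""
        cellular = 1.0 - self.debris_fraction
        return np.array(
            [
                cellular * self.class_mix["singlet"],
                cellular * self.class_mix["small_aggregate"],
                cellular * self.class_mix["large_aggregate"],
                self.debris_fraction,
            ]
        )


# ---------------------------------------------------------------------------
# rasterization helpers


def _ellipse_mask(shape, center, a, b, theta) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def cell_mask(cell: CellSpec, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize one cell as a boolean ellipse on the event grid."""
    return _ellipse_mask(shape, cell.center, cell.radius, cell.semi_minor, cell.orientation)


def union_mask(cells, shape) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    for c in cells:
        out |= cell_mask(c, shape)
    return out


def _is_connected(mask: np.ndarray) -> bool:
    if not mask.any():
        return False
    _, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    return n == 1


def _cell_in_bounds(cell: CellSpec, shape: tuple[int, int]) -> bool:
    r, c = cell.center
    # bounding radius of the ellipse is the semi-major axis
    a = cell.radius
    return a <= r <= shape[0] - 1 - a and a <= c <= shape[1] - 1 - a


# ---------------------------------------------------------------------------
# rendering


def render_event(spec: EventSpec, model: IntensityModel, seed: int) -> EventImageSet:
    """Render one event into four aligned channel images.

    The expected photon signal per channel is built from the cell geometry,
    blurred by ``spec.blur_sigma`` (defocus emulation), then corrupted by
    Poisson shot noise and additive Gaussian read noise and quantized to
    ``uint16`` on a 0–1023 scale. Bit-identical output for identical
    ``(spec, model, seed)``.

    Raises
    ------
    ValueError
        If any cell's disk extends outside the image bounds (events are
        rejected, never clipped).
    """
    shape = spec.image_size
    for cell in spec.cells:
        if not _cell_in_bounds(cell, shape):
            raise ValueError(f"cell at {cell.center} extends outside image bounds {shape}")

    rng = np.random.default_rng(seed)
    expected = {ch: np.full(shape, model.background[ch], dtype=float) for ch in CHANNELS}

    for cell in spec.cells:
        mask = cell_mask(cell, shape)
        npix = int(mask.sum())
        if npix == 0:
            continue
        amp02 = rng.lognormal(
            model.locations[("Ch02", cell.state)], model.scales[("Ch02", cell.state)]
        )
        amp05 = rng.lognormal(
            model.locations[("Ch05", cell.state)], model.scales[("Ch05", cell.state)]
        )
        depth = model.bf_absorbance * rng.uniform(0.8, 1.2)
        speckle = rng.lognormal(0.0, model.ssc_speckle_sigma, size=npix)
        expected["Ch02"][mask] += amp02
        expected["Ch05"][mask] += amp05
        expected["Ch01"][mask] -= depth
        expected["Ch06"][mask] += model.ssc_amplitude * speckle

    for row, col, radius in spec.debris_specks:
        mask = _ellipse_mask(shape, (row, col), radius, radius, 0.0)
        npix = int(mask.sum())
        if npix == 0:
            continue
        expected["Ch01"][mask] -= model.debris_bf_contrast * rng.uniform(0.7, 1.1)
        expected["Ch06"][mask] += model.debris_ssc_amplitude * rng.uniform(0.5, 1.5)

    images: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        signal = expected[ch]
        if spec.blur_sigma > 0:
            signal = ndimage.gaussian_filter(signal, spec.blur_sigma)
        signal = np.clip(signal, 0.0, None)
        noisy = rng.poisson(signal) + rng.normal(0.0, model.read_noise_sigma, size=shape)
        images[ch] = np.clip(np.rint(noisy), 0, MAX_COUNTS).astype(np.uint16)

    return EventImageSet(event_id="event", channels=images, pixel_scale_um=spec.pixel_scale_um)


# ---------------------------------------------------------------------------
# geometry sampling


def _sample_aggregate_geometry(rng, n_cells, config: SampleConfig, states):
    """Place ``n_cells`` touching/overlapping cells by sequential attachment.

    Each new cell is attached to a uniformly chosen existing cell at a
    uniform angle and a centre distance of U[0.8, 1.2] x (sum of radii),
    rejection-sampled until the rasterized union of cells stays a single
    8-connected component inside the image bounds.
    """
    shape = config.image_size
    r_lo, r_hi = config.radius_range

    def new_cell(center, state):
        return CellSpec(
            center=center,
            radius=rng.uniform(r_lo, r_hi),
            state=state,
            eccentricity=rng.uniform(0.0, config.eccentricity_max),
            orientation=rng.uniform(0.0, np.pi),
        )

    for _restart in range(50):
        jitter = min(shape) / 8.0
        center0 = (
            shape[0] / 2.0 + rng.uniform(-jitter, jitter),
            shape[1] / 2.0 + rng.uniform(-jitter, jitter),
        )
        cells = [new_cell(center0, states[0])]
        if not _cell_in_bounds(cells[0], shape):
            continue
        ok = True
        for k in range(1, n_cells):
            placed = False
            for _attempt in range(200):
                anchor = cells[int(rng.integers(len(cells)))]
                radius = rng.uniform(r_lo, r_hi)
                dist = rng.uniform(0.8, 1.2) * (anchor.radius + radius)
                angle = rng.uniform(0.0, 2.0 * np.pi)
                center = (
                    anchor.center[0] + dist * np.sin(angle),
                    anchor.center[1] + dist * np.cos(angle),
                )
                cand = CellSpec(
                    center=center,
                    radius=radius,
                    state=states[k],
                    eccentricity=rng.uniform(0.0, config.eccentricity_max),
                    orientation=rng.uniform(0.0, np.pi),
                )
                if not _cell_in_bounds(cand, shape):
                    continue
                if _is_connected(union_mask(cells + [cand], shape)):
                    cells.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return tuple(cells)
    raise RuntimeError(f"could not place {n_cells}-cell aggregate inside {shape} image")


def _sample_event_spec(rng, event_class, config: SampleConfig) -> EventSpec:
    shape = config.image_size

    if rng.uniform() < config.out_of_focus_fraction:
        blur = rng.uniform(*config.blur_out_of_focus)
    else:
        blur = rng.uniform(*config.blur_in_focus)

    if event_class == "debris":
        n_specks = int(rng.integers(1, 4))
        jitter = min(shape) / 6.0
        specks = tuple(
            (
                shape[0] / 2.0 + rng.uniform(-jitter, jitter),
                shape[1] / 2.0 + rng.uniform(-jitter, jitter),
                rng.uniform(0.7, 1.5),
            )
            for _ in range(n_specks)
        )
        return EventSpec(
            event_class="debris",
            cells=(),
            blur_sigma=blur,
            image_size=shape,
            pixel_scale_um=config.pixel_scale_um,
            debris_specks=specks,
        )

    if event_class == "singlet":
        n_cells = 1
    elif event_class == "small_aggregate":
        lo, hi = config.small_aggregate_cells
        n_cells = int(rng.integers(lo, hi + 1))
    else:
        lo, hi = config.large_aggregate_cells
        n_cells = int(rng.integers(lo, hi + 1))

    state_names = list(config.state_mix.keys())
    state_probs = np.array([config.state_mix[s] for s in state_names])
    states = tuple(str(s) for s in rng.choice(state_names, size=n_cells, p=state_probs))

    cells = _sample_aggregate_geometry(rng, n_cells, config, states)
    return EventSpec(
        event_class=event_class,
        cells=cells,
        blur_sigma=blur,
        image_size=shape,
        pixel_scale_um=config.pixel_scale_um,
    )


def generate_sample(
    config: SampleConfig, seed: int
) -> tuple[list[EventImageSet], list[EventTruth]]:
    """Generate a fully labelled synthetic sample.

    Event classes are drawn by one seeded multinomial over
    (singlet, small aggregate, large aggregate, debris) and shuffled into a
    random acquisition order; per-cell states follow ``config.state_mix``.
    Event ``i`` uses the derived seed ``seed + i`` for rendering, so any
    event can be re-rendered in isolation.
    """
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(config.n_events, config.event_class_probs)
    classes = np.repeat(np.array(EVENT_CLASSES, dtype=object), counts)
    classes = rng.permutation(classes)

    events: list[EventImageSet] = []
    truths: list[EventTruth] = []
    for i, event_class in enumerate(classes):
        event_seed = seed + i
        geom_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=event_seed, spawn_key=(1,))
        )
        spec = _sample_event_spec(geom_rng, event_class, config)
        image = render_event(spec, config.model, event_seed)
        event_id = f"ev{i:05d}"
        image.event_id = event_id
        events.append(image)
        truths.append(
            EventTruth(
                event_id=event_id,
                event_class=spec.event_class,
                n_cells=len(spec.cells),
                states=tuple(c.state for c in spec.cells),
                blur_sigma=spec.blur_sigma,
                seed=event_seed,
            )
        )
    return events, truths


def single_state_config(state: str, base: SampleConfig | None = None, n_events: int = 200) -> SampleConfig:
    """All-singlet, single-state, in-focus variant of a config.

    Used for gate calibration and for gating-recovery checks, where a pure
    population of known physiological state is required.
    """
    base = base or SampleConfig()
    return replace(
        base,
        n_events=n_events,
        class_mix={"singlet": 1.0, "small_aggregate": 0.0, "large_aggregate": 0.0},
        debris_fraction=0.0,
        state_mix={s: (1.0 if s == state else 0.0) for s in CELL_STATES},
        out_of_focus_fraction=0.0,
    )


# ---------------------------------------------------------------------------
# I/O


def write_sample(events, truths, out_dir, overwrite: bool = False) -> Path:
    """Write one multi-page TIFF per event plus a CSV manifest.

    TIFF pages are stored in the order Ch01, Ch02, Ch05, Ch06 as 16-bit
    unsigned grey. Returns the manifest path; ``read_sample`` round-trips
    the pixel data bit-exactly.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} is not empty; pass overwrite=True")
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for event, truth in zip(events, truths, strict=True):
        fname = f"{truth.event_id}.tif"
        stack = np.stack([event[ch] for ch in CHANNELS])
        tifffile.imwrite(out_dir / fname, stack.astype(np.uint16), photometric="minisblack")
        rows.append(
            {
                "event_id": truth.event_id,
                "file": fname,
                "pixel_scale_um": event.pixel_scale_um,
                "event_class": truth.event_class,
                "n_cells": truth.n_cells,
                "states": ";".join(truth.states),
                # repr keeps the shortest exactly round-tripping decimal form
                "blur_sigma": repr(truth.blur_sigma),
                "seed": truth.seed,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_sample(manifest_path) -> tuple[list[EventImageSet], list[EventTruth]]:
    """Load a sample written by :func:`write_sample`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path, keep_default_na=False, float_precision="round_trip")
    events: list[EventImageSet] = []
    truths: list[EventTruth] = []
    for row in df.itertuples(index=False):
        stack = tifffile.imread(base / row.file)
        channels = {ch: np.asarray(stack[k]) for k, ch in enumerate(CHANNELS)}
        events.append(
            EventImageSet(
                event_id=str(row.event_id),
                channels=channels,
                pixel_scale_um=float(row.pixel_scale_um),
            )
        )
        states = tuple(s for s in str(row.states).split(";") if s)
        truths.append(
            EventTruth(
                event_id=str(row.event_id),
                event_class=str(row.event_class),
                n_cells=int(row.n_cells),
                states=states,
                blur_sigma=float(row.blur_sigma),
                seed=int(row.seed),
            )
        )
    return events, truths
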