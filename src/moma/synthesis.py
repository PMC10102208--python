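"""Synthetic H&E-like slides, concept textures and survival cohorts.

Every downstream stage (tiling, stain normalization, feature extraction,
MIL training, survival modeling, interpretation) is testable against data
generated here with known ground truth: slides are composed in optical
density from a known two-stain matrix, slide labels are planted as the
presence of tumor-texture regions, and survival times follow a Weibull model
with covariate-dependent scale and controllable right censoring.

Textures are procedural (dots / stripes / blobs with concept-specific
density, frequency and size), not photorealistic: the design goal is
determinism and linear separability in simple filter statistics, which is
what the tests need.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONCEPTS = ("TUM", "STR", "LYM", "MUS", "MUC", "ADI", "DEB")
"""Seven pathology concepts: colorectal adenocarcinoma epithelium (TUM),
cancer-associated stroma (STR), lymphocytes (LYM), smooth muscle (MUS),
mucus (MUC), adipose tissue (ADI) and tissue debris (DEB)."""

CONCEPT_CODES = {c: i + 1 for i, c in enumerate(CONCEPTS)}  # 0 = background

#: Standard H&E optical-density stain vectors (hematoxylin, eosin columns),
#: unit-norm and nonnegative.
DEFAULT_STAIN_MATRIX = np.array(
    [[0.65, 0.07],
     [0.70, 0.99],
     [0.29, 0.11]]
)
DEFAULT_STAIN_MATRIX = DEFAULT_STAIN_MATRIX / np.linalg.norm(
    DEFAULT_STAIN_MATRIX, axis=0, keepdims=True)

ILLUMINANT = 255.0  # white point per channel for 8-bit synthesis


@dataclass
class SlideSpec:
    """Recipe for one synthetic slide.

    ``concept_layout`` is a list of ``((row0, col0, row1, col1), concept)``
    with half-open pixel rectangles. ``background_fraction`` is the target
    fraction of unstained area; the degenerate value 1.0 renders a pure
    illuminant slide regardless of layout.
    """

    width_px: int
    height_px: int
    concept_layout: list = field(default_factory=list)
    stain_matrix: np.ndarray = field(default_factory=lambda: DEFAULT_STAIN_MATRIX.copy())
    noise_sd: float = 0.01
    background_fraction: float = 0.0

    def validate(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("slide dimensions must be positive")
        M = np.asarray(self.stain_matrix, dtype=float)
        if M.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2")
        if np.any(M < 0):
            raise ValueError("stain_matrix entries must be nonnegative")
        if not np.allclose(np.linalg.norm(M, axis=0), 1.0, atol=1e-6):
            raise ValueError("stain_matrix columns must have unit norm")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must be in [0, 1]")
        for (r0, c0, r1, c1), concept in self.concept_layout:
            if concept not in CONCEPTS:
                raise ValueError(f"unknown concept {concept!r}")
            if not (0 <= r0 < r1 <= self.height_px and 0 <= c0 < c1 <= self.width_px):
                raise ValueError(f"region {(r0, c0, r1, c1)} outside slide bounds")

    def to_json(self) -> dict:
        return {
            "width_px": self.width_px,
            "height_px": self.height_px,
            "concept_layout": [[list(map(int, rect)), concept]
                               for rect, concept in self.concept_layout],
            "stain_matrix": np.asarray(self.stain_matrix).tolist(),
            "noise_sd": self.noise_sd,
            "background_fraction": self.background_fraction,
        }


# --------------------------------------------------------------------------
# concept textures (stain-concentration space)
# --------------------------------------------------------------------------

def _concept_concentrations(concept: str, h: int, w: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Return a (2, h, w) hematoxylin/eosin concentration map for a concept.

    Generator recipe (the contract the texture tests rely on):

    - TUM: dense medium dots of hematoxylin (nuclear crowding), eosin wash.
    - STR: diagonal eosin stripes, sparse hematoxylin.
    - LYM: very dense small hematoxylin dots, almost no eosin.
    - MUS: low-frequency horizontal eosin bands.
    - MUC: faint smooth wash (low OD, low variance).
    - ADI: near-white field with large circular white blobs outlined by a
      thin eosin rim (>= 1 blob guaranteed).
    - DEB: coarse random blotches of both stains.
    """
    hem = np.zeros((h, w))
    eos = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w]

    def add_dots(channel, n, radius, amp):
        cy = rng.uniform(0, h, size=n)
        cx = rng.uniform(0, w, size=n)
        for y0, x0 in zip(cy, cx):
            d2 = (yy - y0) ** 2 + (xx - x0) ** 2
            channel += amp * np.exp(-d2 / (2.0 * radius**2))

    if concept == "TUM":
        add_dots(hem, n=max(6, (h * w) // 180), radius=max(2.0, h / 22), amp=0.9)
        eos += 0.25
    elif concept == "STR":
        phase = rng.uniform(0, 2 * np.pi)
        eos += 0.45 + 0.35 * np.sin(2 * np.pi * (xx + yy) / (h / 3.0) + phase)
        hem += 0.08
    elif concept == "LYM":
        add_dots(hem, n=max(20, (h * w) // 45), radius=max(1.0, h / 55), amp=1.1)
        eos += 0.06
    elif concept == "MUS":
        phase = rng.uniform(0, 2 * np.pi)
        eos += 0.55 + 0.30 * np.sin(2 * np.pi * yy / (h / 1.5) + phase)
        hem += 0.15
    elif concept == "MUC":
        base = 0.12 + 0.04 * rng.standard_normal()
        eos += base
        hem += 0.5 * base
    elif concept == "ADI":
        eos += 0.30
        n_blobs = max(1, int(rng.integers(1, 4)))
        for _ in range(n_blobs):
            r = rng.uniform(0.22, 0.38) * min(h, w)
            y0 = rng.uniform(r, h - r) if h > 2 * r else h / 2
            x0 = rng.uniform(r, w - r) if w > 2 * r else w / 2
            d = np.sqrt((yy - y0) ** 2 + (xx - x0) ** 2)
            inside = d < r
            rim = (d >= r) & (d < r + max(1.5, 0.06 * r))
            eos[inside] = 0.0  # near-white interior
            hem[inside] = 0.0
            eos[rim] += 0.6
    elif concept == "DEB":
        coarse = rng.standard_normal((max(2, h // 8), max(2, w // 8)))
        coarse = np.kron(coarse, np.ones((8, 8)))[:h, :w]
        eos += 0.35 * (coarse > 0.3)
        hem += 0.45 * (coarse < -0.3)
    else:
        raise ValueError(f"unknown concept id {concept!r}")

    return np.stack([np.clip(hem, 0, 2.5), np.clip(eos, 0, 2.5)])


def concentrations_to_rgb(conc: np.ndarray, stain_matrix: np.ndarray,
                          noise_sd: float = 0.0,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Compose RGB from (2, h, w) stain concentrations via the OD model.

    OD = M @ C (+ Gaussian noise in OD units); intensity follows the inverse
    of the optical-density transform used in preprocessing:
    ``I = (I0 + 1) * 10**(-OD) - 1``.
    """
    od = np.tensordot(np.asarray(stain_matrix), conc, axes=(1, 0))  # (3, h, w)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        od = od + rng.normal(0.0, noise_sd, size=od.shape)
    od = np.clip(od, 0.0, None)
    rgb = (ILLUMINANT + 1.0) * np.power(10.0, -od) - 1.0
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8).transpose(1, 2, 0)


def make_concept_texture(concept: str, size: int, seed: int,
                         stain_matrix: np.ndarray | None = None,
                         noise_sd: float = 0.02) -> np.ndarray:
    """Render one (size, size, 3) uint8 RGB texture patch for a concept.

    Deterministic given ``seed``; distinct concepts are linearly separable
    in simple mean/variance/edge statistics by construction.
    """
    if concept not in CONCEPTS:
        raise ValueError(f"unknown concept id {concept!r}; valid: {CONCEPTS}")
    if size < 32:
        raise ValueError("texture size must be >= 32 pixels")
    rng = np.random.default_rng(seed)
    M = DEFAULT_STAIN_MATRIX if stain_matrix is None else stain_matrix
    conc = _concept_concentrations(concept, size, size, rng)
    return concentrations_to_rgb(conc, M, noise_sd=noise_sd, rng=rng)


def make_stain_gradient_concentrations(height: int = 64, width: int = 64,
                                       max_concentration: float = 2.4) -> np.ndarray:
    """A (2, h, w) concentration map sweeping from pure hematoxylin (left)
    to pure eosin (right) with amplitude increasing down the rows.

    A stain-calibration pattern: it guarantees strong near-pure pixels of
    both stains, so the extreme-angle stain estimation can recover the
    planted basis to high precision from its rendering.
    """
    # 20% pure-stain plateaus at both ends so the robust extreme-angle
    # percentiles fall well inside the pure-stain pixel sets even after the
    # transparent-pixel OD filter
    t = np.clip((np.linspace(0.0, 1.0, width)[None, :] - 0.2) / 0.6, 0.0, 1.0)
    amp = np.linspace(0.6, 1.0, height)[:, None] * max_concentration
    return np.stack([amp * (1.0 - t), amp * t])


# --------------------------------------------------------------------------
# slide rendering
# --------------------------------------------------------------------------

def render_slide(spec: SlideSpec, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Render a slide to (RGB uint8 image, int mask of concept codes).

    The mask labels every pixel with its concept code (0 = background). The
    mask depends only on the layout, so different seeds on the same spec give
    identical masks with different noise/texture realizations.
    """
    spec.validate()
    h, w = spec.height_px, spec.width_px
    mask = np.zeros((h, w), dtype=np.uint8)
    conc = np.zeros((2, h, w))
    # texture content and noise use separate streams so the mask/texture of
    # region i does not shift when noise is toggled
    rng_tex = np.random.default_rng((seed, 1))
    rng_noise = np.random.default_rng((seed, 2))
    if spec.background_fraction < 1.0:
        for (r0, c0, r1, c1), concept in spec.concept_layout:
            region = _concept_concentrations(concept, r1 - r0, c1 - c0, rng_tex)
            conc[:, r0:r1, c0:c1] = region
            mask[r0:r1, c0:c1] = CONCEPT_CODES[concept]
    image = concentrations_to_rgb(conc, spec.stain_matrix, spec.noise_sd,
                                  rng_noise if spec.noise_sd > 0 else None)
    return image, mask


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

MANIFEST_COLUMNS = ["slide_id", "path", "label", "time", "event", "partition"]


def validate_manifest(manifest: pd.DataFrame) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    if manifest["slide_id"].duplicated().any():
        raise ValueError("slide ids must be unique")
    has_time = manifest["time"].notna()
    if (manifest.loc[has_time, "time"] <= 0).any():
        raise ValueError("survival times must be positive")
    ev = manifest["event"].dropna()
    if not ev.isin([0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    validate_manifest(manifest)
    cols = MANIFEST_COLUMNS + [c for c in manifest.columns if c not in MANIFEST_COLUMNS]
    manifest[cols].to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, dtype={"slide_id": str, "partition": str})
    validate_manifest(manifest)
    return manifest


def simulate_survival_cohort(n: int, coef, lambda0: float, kappa: float,
                             censor_rate: float, seed: int) -> pd.DataFrame:
    """Simulate a right-censored Weibull survival cohort.

    Covariates ``x ~ N(0, I)``; event times ``T ~ Weibull`` with shape
    ``kappa`` and per-subject scale ``lambda0 * exp(coef . x)``. Censoring
    times are uniform on (0, q) with q calibrated by bisection so the
    realized censoring fraction approximates ``censor_rate``. Covariates are
    returned as columns ``x0..x{d-1}`` alongside the manifest fields.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")
    if lambda0 <= 0 or kappa <= 0:
        raise ValueError("lambda0 and kappa must be positive")
    coef = np.atleast_1d(np.asarray(coef, dtype=float))
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, coef.size))
    scale = lambda0 * np.exp(x @ coef)
    t_event = scale * rng.weibull(kappa, size=n)
    t_event = np.maximum(t_event, 1e-9)

    if censor_rate == 0.0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        u = rng.random(n)

        def censored_fraction(q: float) -> float:
            return float(np.mean(q * u < t_event))

        lo, hi = 1e-9, float(np.max(t_event)) / max(np.min(u), 1e-12) + 1.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if censored_fraction(mid) > censor_rate:
                lo = mid
            else:
                hi = mid
        q = 0.5 * (lo + hi)
        t_cens = np.maximum(q * u, 1e-9)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)

    manifest = pd.DataFrame({
        "slide_id": [f"s{i:05d}" for i in range(n)],
        "path": "",
        "label": np.nan,
        "time": time,
        "event": event,
        "partition": "",
    })
    for j in range(coef.size):
        manifest[f"x{j}"] = x[:, j]
    return manifest


def simulate_labeled_cohort(n_slides: int, grid: tuple[int, int] = (4, 4),
                            tile_px: int = 64, m_tumor: int = 2, seed: int = 0,
                            positive_fraction: float = 0.5,
                            noise_sd: float = 0.02) -> tuple[list[SlideSpec], pd.DataFrame]:
    """Build slide specs whose class label is planted in the concept layout.

    Each slide is a ``grid`` of square ``tile_px`` regions filled with
    non-tumor concepts; positive slides additionally receive at least
    ``m_tumor`` tumor (TUM) regions, negative slides receive none. The label
    rule — positive iff the layout holds >= ``m_tumor`` tumor regions — is a
    deterministic function of the layout, recorded in the manifest together
    with the planted tumor tile coordinates (JSON list in ``tumor_tiles``).
    """
    rng = np.random.default_rng(seed)
    rows, cols = grid
    non_tumor = [c for c in CONCEPTS if c != "TUM"]
    specs, records = [], []
    n_pos = int(round(n_slides * positive_fraction))
    labels = np.array([1] * n_pos + [0] * (n_slides - n_pos))
    rng.shuffle(labels)
    for i, label in enumerate(labels):
        layout, tumor_tiles = [], []
        cells = [(r, c) for r in range(rows) for c in range(cols)]
        if label == 1:
            k = int(rng.integers(m_tumor, max(m_tumor, rows * cols // 2) + 1))
            chosen = rng.choice(len(cells), size=k, replace=False)
            tumor_cells = {cells[j] for j in chosen}
        else:
            tumor_cells = set()
        for r, c in cells:
            concept = "TUM" if (r, c) in tumor_cells else non_tumor[rng.integers(len(non_tumor))]
            rect = (r * tile_px, c * tile_px, (r + 1) * tile_px, (c + 1) * tile_px)
            layout.append((rect, concept))
            if concept == "TUM":
                tumor_tiles.append([r, c])
        specs.append(SlideSpec(width_px=cols * tile_px, height_px=rows * tile_px,
                               concept_layout=layout, noise_sd=noise_sd))
        records.append({
            "slide_id": f"slide{i:04d}", "path": "", "label": int(label),
            "time": np.nan, "event": np.nan, "partition": "",
            "tumor_tiles": json.dumps(tumor_tiles),
        })
    manifest = pd.DataFrame(records)
    assert all((len(json.loads(t)) >= m_tumor) == bool(l)
               for t, l in zip(manifest["tumor_tiles"], manifest["label"]))
    return specs, manifest


def write_cohort(specs: list[SlideSpec], manifest: pd.DataFrame,
                 out_dir: str | Path, seed: int = 0,
                 image_format: str = "png") -> pd.DataFrame:
    """Render a cohort to disk: images, masks, manifest.csv and a JSON
    sidecar with the generating specs and seed. Returns the manifest with
    file paths filled in."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    (out_dir / "slides").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    sidecar = {"seed": seed, "slides": {}}
    for i, spec in enumerate(specs):
        sid = manifest.iloc[i]["slide_id"]
        image, mask = render_slide(spec, seed=seed + i)
        img_path = out_dir / "slides" / f"{sid}.{image_format}"
        if image_format == "tiff":
            import tifffile
            tifffile.imwrite(img_path, image)
        else:
            iio.imwrite(img_path, image)
        iio.imwrite(out_dir / "masks" / f"{sid}.png", mask)
        manifest.loc[manifest.index[i], "path"] = str(img_path)
        sidecar["slides"][sid] = spec.to_json()
    write_manifest(manifest, out_dir / "manifest.csv")
    with open(out_dir / "cohort_spec.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return manifest
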