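"""Study orchestration: model comparisons, orientation scans, lateral
separation, conductivity sweep and SNR planning.

The three main analyses mirror how volume-conductor models are evaluated for
magnetospinography:

* **model comparison** — median relative error and squared correlation
  between every pair of models over the medial sources, for all cardinal
  orientations pooled and per axis;
* **orientation scan** — per-source eigenfield intensity ratios and the
  angle between the dominant source orientation and the inferior-superior
  axis, quantifying how bone reshapes orientation sensitivity;
* **lateral separation** — how distinguishable the left and right
  paramedial sources (8 mm apart) of each cord slice are, including the
  asymmetry of the field extrema ("poles") that bone introduces.

A small SNR helper converts a field amplitude, sensor noise density and
bandwidth into the trial count needed for a 0 dB evoked average.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analytic import leadfield_analytic, ANALYTIC_TAGS
from .bem import (DEFAULT_CONDUCTIVITIES, build_bem_system, conductor_model,
                  leadfield_bem)
from .geometry import (GeometryConfig, GeometryBundle, build_geometry,
                       save_geometry, LEFT_RING, RIGHT_RING)
from .leadfield import LeadField
from .metrics import (eigenfields, principal_orientation_angle,
                      relative_error, squared_correlation)

__all__ = [
    "StudyConfig", "Study", "ModelComparisonMatrix", "OrientationScanResult",
    "LateralSeparationResult", "MODEL_LABELS",
    "run_model_comparison", "run_orientation_scan", "run_lateral_separation",
    "run_conductivity_sweep", "snr_trial_count", "run_study",
]

#: canonical model tags -> display labels
MODEL_LABELS = {
    "inf": "Inf", "sphere": "SS", "corrected-sphere": "CS",
    "1c-lc": "1c LC", "3c-lc": "3c LC", "4c-lc": "4c LC", "5c-lc": "5c LC",
    "5c-lci": "5c LCi",
}

DEFAULT_MODELS = tuple(MODEL_LABELS)

#: cardinal orientation index per axis label
ORIENTATION_SETS = {"all": (0, 1, 2), "R-L": (2,), "I-S": (0,), "A-P": (1,)}


@dataclass(frozen=True)
class StudyConfig:
    """Full study parameterisation; deterministic given the seed."""

    geometry: GeometryConfig = field(
        default_factory=lambda: GeometryConfig(density=0.5))
    models: tuple[str, ...] = DEFAULT_MODELS
    conductivities: tuple[tuple[str, float], ...] = tuple(
        sorted(DEFAULT_CONDUCTIVITIES.items()))
    well_sampled: tuple[int, int] = (10, 50)   # inclusive slice range
    t9_fraction: float = 0.6                   # arc fraction of the T9 slice
    out_dir: str = "study_out"
    seed: int = 0

    def __post_init__(self) -> None:
        for tag in self.models:
            if tag not in MODEL_LABELS:
                raise ValueError(f"unknown model tag {tag!r}")
        lo, hi = self.well_sampled
        if not (0 <= lo <= hi <= 60):
            raise ValueError("well-sampled slice range must lie within 0..60")

    @property
    def sigma(self) -> dict[str, float]:
        return dict(self.conductivities)

    def to_yaml(self, path: str | Path) -> Path:
        data = asdict(self)
        data["geometry"] = asdict(self.geometry)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["geometry"] = GeometryConfig(**data["geometry"])
        data["models"] = tuple(data["models"])
        data["conductivities"] = tuple(
            (k, float(v)) for k, v in data["conductivities"])
        data["well_sampled"] = tuple(data["well_sampled"])
        return cls(**data)

    def config_hash(self) -> str:
        data = asdict(self)
        data["geometry"] = asdict(self.geometry)
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class ModelComparisonMatrix:
    """Median RE / CC^2 between model pairs over the medial sources."""

    models: list[str]
    re: dict[str, np.ndarray]     # orientation set -> (m, m)
    cc2: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for oset in self.re:
            for i, a in enumerate(self.models):
                for j, b in enumerate(self.models):
                    rows.append((a, b, oset, self.re[oset][i, j],
                                 self.cc2[oset][i, j]))
        return pd.DataFrame(rows, columns=[
            "model_a", "model_b", "orientation_set", "median_RE",
            "median_CC2"])


@dataclass
class OrientationScanResult:
    """Eigenfield ratios and orientation angles per model and slice."""

    table: pd.DataFrame   # model, slice, s1, s2, s3, ratio12, angle_deg, ...
    well_sampled: tuple[int, int]

    def summary(self) -> pd.DataFrame:
        lo, hi = self.well_sampled
        sel = self.table[(self.table.slice_index >= lo)
                         & (self.table.slice_index <= hi)]
        return sel.groupby("model", sort=False).agg(
            median_ratio12=("ratio12", "median"),
            median_angle_deg=("angle_deg", "median"),
            median_tangent_error_deg=("angle_vs_tangent_deg", "median"),
        ).reset_index()


@dataclass
class LateralSeparationResult:
    """Left- vs right-medial separability per model and slice."""

    table: pd.DataFrame   # model, slice, RE, CC2, pole metrics (left source)

    def summary(self) -> pd.DataFrame:
        return self.table.groupby("model", sort=False).agg(
            median_RE=("RE", "median"), median_CC2=("CC2", "median"),
        ).reset_index()


# ---------------------------------------------------------------------------
# Study driver
# ---------------------------------------------------------------------------

class Study:
    """Caches the geometry, BEM systems and lead fields for one config.

    Lead fields are computed for the medial sources plus the left/right
    ring sources of every slice (what the three analyses consume), for the
    three cardinal unit dipoles.
    """

    def __init__(self, config: StudyConfig | None = None) -> None:
        self.config = config or StudyConfig()
        self._bundle: GeometryBundle | None = None
        self._leadfields: dict[str, LeadField] = {}
        self._systems: dict = {}
        self.timings: dict[str, float] = {}

    # -- lazy pieces -------------------------------------------------------

    @property
    def bundle(self) -> GeometryBundle:
        if self._bundle is None:
            t0 = time.perf_counter()
            self._bundle = build_geometry(self.config.geometry)
            self.timings["geometry"] = time.perf_counter() - t0
        return self._bundle

    @property
    def t9_slice(self) -> int:
        n = self.bundle.sources.n_slices
        return int(round(self.config.t9_fraction * (n - 1)))

    def source_indices(self) -> np.ndarray:
        """Medial plus left/right ring sources, slice-major order."""
        src = self.bundle.sources
        keep = np.isin(src.ring_position, (0, LEFT_RING, RIGHT_RING))
        return np.flatnonzero(keep)

    def leadfield(self, tag: str) -> LeadField:
        if tag not in self._leadfields:
            self._leadfields[tag] = self._compute_leadfield(tag)
        return self._leadfields[tag]

    def _compute_leadfield(self, tag: str) -> LeadField:
        t0 = time.perf_counter()
        idx = self.source_indices()
        if tag in ANALYTIC_TAGS:
            lf = leadfield_analytic(tag, self.bundle, source_indices=idx)
        else:
            base, iso = tag.split("-")[0], tag.endswith("lci")
            system = self._systems.get(base)
            if system is None:
                model = conductor_model(self.bundle, base, self.config.sigma,
                                        isolated=True if base == "5c" else False)
                system = build_bem_system(model)
                self._systems[base] = system
            lf = leadfield_bem(base, self.bundle, self.config.sigma,
                               isolated=iso, source_indices=idx, system=system)
        lf.model_tag = MODEL_LABELS[tag]
        self.timings[f"leadfield:{tag}"] = time.perf_counter() - t0
        return lf

    def _rows_for(self, lf: LeadField, ring: int) -> np.ndarray:
        """(n_slices,) positions inside the computed lead field."""
        meta = lf.sources
        sel = meta.index[meta.ring_position == ring].to_numpy()
        order = np.argsort(meta.loc[sel, "slice_index"].to_numpy())
        return sel[order]

    # -- analyses ----------------------------------------------------------

    def model_comparison(self) -> ModelComparisonMatrix:
        """Median RE / CC^2 matrices over medial sources and orientations.

        Per-source-per-orientation values are pooled, then the median is
        taken per model pair and orientation set.
        """
        tags = list(self.config.models)
        lfs = {t: self.leadfield(t) for t in tags}
        medial = {t: lfs[t].matrix[:, self._rows_for(lfs[t], 0), :]
                  for t in tags}
        m = len(tags)
        re = {o: np.zeros((m, m)) for o in ORIENTATION_SETS}
        cc2 = {o: np.eye(m) for o in ORIENTATION_SETS}
        for i in range(m):
            for j in range(i, m):
                A, B = medial[tags[i]], medial[tags[j]]
                for oset, ks in ORIENTATION_SETS.items():
                    res = [relative_error(A[:, s, k], B[:, s, k])
                           for s in range(A.shape[1]) for k in ks]
                    ccs = [squared_correlation(A[:, s, k], B[:, s, k])
                           for s in range(A.shape[1]) for k in ks]
                    re[oset][i, j] = re[oset][j, i] = np.median(res)
                    cc2[oset][i, j] = cc2[oset][j, i] = np.median(ccs)
        labels = [MODEL_LABELS[t] for t in tags]
        return ModelComparisonMatrix(labels, re, cc2)

    def orientation_scan(self) -> OrientationScanResult:
        """Eigenfield SVD per model and medial source."""
        rows = []
        is_axis = np.array([1.0, 0.0, 0.0])
        src = self.bundle.sources
        for tag in self.config.models:
            lf = self.leadfield(tag)
            rset = self._rows_for(lf, 0)
            slices = lf.sources.loc[rset, "slice_index"].to_numpy()
            for s, row in zip(slices, rset):
                ef = eigenfields(lf.matrix[:, row, :])
                angle = principal_orientation_angle(ef, is_axis)
                tangent = src.frames[src.index_of(int(s), 0), 0]
                tangent_angle = math.degrees(math.acos(
                    min(1.0, abs(float(tangent[0])))))
                angle_vs_tangent = abs(principal_orientation_angle(ef, tangent))
                rows.append((MODEL_LABELS[tag], int(s), *ef.S, ef.ratio12,
                             ef.ratio13, angle, tangent_angle,
                             angle_vs_tangent))
        table = pd.DataFrame(rows, columns=[
            "model", "slice_index", "s1", "s2", "s3", "ratio12", "ratio13",
            "angle_deg", "tangent_angle_deg", "angle_vs_tangent_deg"])
        return OrientationScanResult(table, self.config.well_sampled)

    def lateral_separation(self) -> LateralSeparationResult:
        """Left vs right paramedial sources driven along the spine tangent.

        RE / CC^2 compare the full 3-axis topographies; the pole-asymmetry
        diagnostics (field extrema and their percentage ratio) are read from
        the primary-axis channels (Y, normal to the back) — the topography
        as conventionally mapped.
        """
        rows = []
        src = self.bundle.sources
        primary = np.arange(self.bundle.sensors.n_channels) % 3 == 1
        for tag in self.config.models:
            lf = self.leadfield(tag)
            left_rows = self._rows_for(lf, LEFT_RING)
            right_rows = self._rows_for(lf, RIGHT_RING)
            slices = lf.sources.loc[left_rows, "slice_index"].to_numpy()
            for s, rl, rr in zip(slices, left_rows, right_rows):
                e_is = src.frames[src.index_of(int(s), 0), 0]
                tl = lf.matrix[:, rl, :] @ e_is
                tr = lf.matrix[:, rr, :] @ e_is
                pos, neg = float(tl[primary].max()), float(tl[primary].min())
                hi = max(abs(pos), abs(neg))
                lo = min(abs(pos), abs(neg))
                rows.append((MODEL_LABELS[tag], int(s),
                             relative_error(tl, tr),
                             squared_correlation(tl, tr),
                             pos, neg, 100.0 * lo / hi))
        table = pd.DataFrame(rows, columns=[
            "model", "slice_index", "RE", "CC2", "left_max_fT_per_nAm",
            "left_min_fT_per_nAm", "left_pole_ratio_pct"])
        return LateralSeparationResult(table)

    def conductivity_sweep(self, bone_sigmas: list[float]) -> pd.DataFrame:
        """s1/s2 at the T9 medial source as the cord/bone contrast varies."""
        if any(s <= 0 for s in bone_sigmas):
            raise ValueError("conductivities must be positive")
        sigma = self.config.sigma
        t9 = self.t9_slice
        idx = np.array([self.bundle.sources.index_of(t9, 0)])
        rows = []
        for sb in bone_sigmas:
            s = dict(sigma)
            s["bone"] = sb
            lf = leadfield_bem("5c", self.bundle, s, source_indices=idx)
            ef = eigenfields(lf.matrix[:, 0, :])
            rows.append((sb, sigma["cord"] / sb, ef.ratio12))
        return pd.DataFrame(rows, columns=[
            "sigma_bone_S_per_m", "cord_bone_ratio", "ratio12_at_t9"])


def snr_trial_count(amplitude_fT: float, noise_fT_per_sqrtHz: float,
                    bandwidth_Hz: float) -> int:
    """Trials needed for a 0 dB evoked average.

    Averaging N trials reduces the noise to ``noise * sqrt(bandwidth / N)``;
    the smallest N with amplitude >= that is ceil((noise sqrt(BW) / A)^2).
    """
    if amplitude_fT <= 0 or noise_fT_per_sqrtHz <= 0 or bandwidth_Hz <= 0:
        raise ValueError("amplitude, noise and bandwidth must be positive")
    n = (noise_fT_per_sqrtHz * math.sqrt(bandwidth_Hz) / amplitude_fT) ** 2
    return max(1, math.ceil(n - 1e-12))


# ---------------------------------------------------------------------------
# Module-level operation wrappers and the full run
# ---------------------------------------------------------------------------

def run_model_comparison(config: StudyConfig) -> ModelComparisonMatrix:
    return Study(config).model_comparison()


def run_orientation_scan(config: StudyConfig) -> OrientationScanResult:
    return Study(config).orientation_scan()


def run_lateral_separation(config: StudyConfig) -> LateralSeparationResult:
    return Study(config).lateral_separation()


def run_conductivity_sweep(config: StudyConfig,
                           bone_sigmas: list[float]) -> pd.DataFrame:
    return Study(config).conductivity_sweep(bone_sigmas)


def run_study(config: StudyConfig, sweep_sigmas: list[float] | None = None
              ) -> Path:
    """Run every analysis and serialise the results bundle.

    Writes the geometry, per-model lead fields (HDF5 + content hash), the
    comparison/orientation/lateral TSV tables, an optional conductivity
    sweep, and a JSON manifest with the config hash and per-stage timings.
    Output content is bit-reproducible for identical configs: the manifest's
    ``content_hashes`` cover every result table and lead-field matrix.
    """
    study = Study(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()

    save_geometry(study.bundle, out / "geometry")
    hashes: dict[str, str] = {}

    lf_dir = out / "leadfields"
    lf_dir.mkdir(exist_ok=True)
    for tag in config.models:
        lf = study.leadfield(tag)
        lf.save_hdf5(lf_dir / f"{tag}.h5")
        hashes[f"leadfield:{tag}"] = lf.content_hash()

    comparison = study.model_comparison()
    comparison.to_frame().to_csv(out / "model_comparison.tsv", sep="\t",
                                 index=False)
    scan = study.orientation_scan()
    scan.table.to_csv(out / "orientation_scan.tsv", sep="\t", index=False)
    scan.summary().to_csv(out / "orientation_summary.tsv", sep="\t",
                          index=False)
    lateral = study.lateral_separation()
    lateral.table.to_csv(out / "lateral_separation.tsv", sep="\t", index=False)

    if sweep_sigmas:
        sweep = study.conductivity_sweep(sweep_sigmas)
        sweep.to_csv(out / "conductivity_sweep.tsv", sep="\t", index=False)

    for tsv in sorted(out.glob("*.tsv")):
        hashes[tsv.name] = hashlib.sha256(tsv.read_bytes()).hexdigest()

    import spinefield
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {"spinefield": spinefield.__version__,
                     "numpy": np.__version__},
        "content_hashes": hashes,
        "timings_s": {k: round(v, 3) for k, v in study.timings.items()},
        "total_s": round(time.perf_counter() - t_start, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    config.to_yaml(out / "study.yaml")
    return out
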