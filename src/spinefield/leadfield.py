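"""Lead-field container and its HDF5 / TSV serialisation.

A lead field maps a unit current dipole (1 nAm) along each cardinal axis at
each source location to the vector of channel readings, in fT per nAm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["LeadField"]

ORIENTATIONS = ("x", "y", "z")


@dataclass
class LeadField:
    """channels x sources x 3 cardinal orientations, fT per nAm."""

    matrix: np.ndarray                  # (C, S, 3)
    model_tag: str
    channels: pd.DataFrame | None = None   # site, axis per channel
    sources: pd.DataFrame | None = None    # per-source metadata
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 3 or self.matrix.shape[2] != 3:
            raise ValueError("lead-field matrix must be (channels, sources, 3)")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("lead-field matrix contains non-finite entries")
        if self.channels is not None and len(self.channels) != self.matrix.shape[0]:
            raise ValueError("channel metadata does not match matrix")
        if self.sources is not None and len(self.sources) != self.matrix.shape[1]:
            raise ValueError("source metadata does not match matrix")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1]

    def triplet(self, source: int) -> np.ndarray:
        """(channels, 3) field topographies of the cardinal dipoles."""
        return self.matrix[:, source, :]

    def topography(self, source: int, moment_nAm: np.ndarray) -> np.ndarray:
        """Field of an arbitrary dipole moment (nAm) by linearity."""
        return self.matrix[:, source, :] @ np.asarray(moment_nAm, dtype=float)

    def content_hash(self) -> str:
        import hashlib
        return hashlib.sha256(np.ascontiguousarray(self.matrix).tobytes()).hexdigest()

    # -- IO -------------------------------------------------------------

    def save_hdf5(self, path: str | Path) -> Path:
        path = Path(path)
        with h5py.File(path, "w") as f:
            d = f.create_dataset("leadfield", data=self.matrix, track_times=False)
            d.attrs["units"] = "fT/nAm"
            f.attrs["model_tag"] = self.model_tag
            if self.channels is not None:
                f.create_dataset(
                    "channels",
                    data=self.channels.to_csv(sep="\t", index=False).encode(),
                    track_times=False)
            if self.sources is not None:
                f.create_dataset(
                    "sources",
                    data=self.sources.to_csv(sep="\t", index=False).encode(),
                    track_times=False)
        return path

    @classmethod
    def load_hdf5(cls, path: str | Path) -> "LeadField":
        import io
        with h5py.File(path, "r") as f:
            matrix = np.asarray(f["leadfield"])
            tag = f.attrs["model_tag"]
            channels = sources = None
            if "channels" in f:
                channels = pd.read_csv(io.BytesIO(f["channels"][()]), sep="\t")
            if "sources" in f:
                sources = pd.read_csv(io.BytesIO(f["sources"][()]), sep="\t")
        return cls(matrix, str(tag), channels, sources)

    def to_frame(self) -> pd.DataFrame:
        """Wide TSV layout: one row per channel x source, 3 value columns."""
        C, S, _ = self.matrix.shape
        return pd.DataFrame({
            "channel": np.repeat(np.arange(C), S),
            "source": np.tile(np.arange(S), C),
            **{f"b_{o}_fT_per_nAm": self.matrix[:, :, k].ravel()
               for k, o in enumerate(ORIENTATIONS)},
        })

    def save_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path
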