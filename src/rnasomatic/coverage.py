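"""Per-base read-depth tracks over transcript space."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gene_models import TranscriptModel


@dataclass
class CoverageTrack:
    """Read depth per base for one sample, keyed by chrom/transcript id."""

    sample_id: str
    depths: dict[str, np.ndarray] = field(default_factory=dict)

    def depth(self, chrom: str, pos: int) -> int:
        arr = self.depths.get(chrom)
        if arr is None or not 0 <= pos < len(arr):
            return 0
        return int(arr[pos])

    def profile(self, model: TranscriptModel) -> np.ndarray:
        """Depth per coding position of ``model``, in coding orientation."""
        arr = self.depths.get(model.chrom)
        if arr is None:
            return np.zeros(model.cds_length, dtype=np.int64)
        pieces = []
        for start, end in model.cds_intervals:
            piece = np.zeros(end - start, dtype=np.int64)
            lo, hi = max(start, 0), min(end, len(arr))
            if hi > lo:
                piece[lo - start : hi - start] = arr[lo:hi]
            pieces.append(piece)
        out = np.concatenate(pieces) if pieces else np.zeros(0, dtype=np.int64)
        if model.strand == "-":
            out = out[::-1]
        return out

    def to_tsv(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tdepth\n")
            for chrom in sorted(self.depths):
                arr = self.depths[chrom]
                for pos in range(len(arr)):
                    fh.write(f"{chrom}\t{pos}\t{int(arr[pos])}\n")

    @classmethod
    def from_tsv(cls, path: Path | str, sample_id: str) -> "CoverageTrack":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": np.int64, "depth": np.int64})
        if list(df.columns) != ["chrom", "pos", "depth"]:
            raise ValueError(f"{path}: expected columns chrom/pos/depth, got {list(df.columns)}")
        depths: dict[str, np.ndarray] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            arr = np.zeros(int(sub["pos"].max()) + 1, dtype=np.int64)
            arr[sub["pos"].to_numpy()] = sub["depth"].to_numpy()
            depths[str(chrom)] = arr
        return cls(sample_id=sample_id, depths=depths)
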