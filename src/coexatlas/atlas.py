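"""Expression atlas container and tab-separated I/O.

An atlas is a genes (or probes) × samples matrix of non-negative,
already-normalized expression values.  The container tracks whether the
values are on the raw or log10 scale so downstream stages can refuse
inputs on the wrong scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RAW = "raw"
LOG10 = "log10"


class AtlasError(ValueError):
    """Raised for malformed atlases or atlas files."""


@dataclass
class ExpressionAtlas:
    """Genes/probes × samples expression matrix.

    Parameters
    ----------
    data:
        DataFrame indexed by gene/probe identifier, one column per sample.
    scale_state:
        Either ``"raw"`` or ``"log10"``.
    gene_map:
        Optional probe → gene-model annotation carried alongside probe-level
        rows (used to discard network edges between probes of one gene).
    """

    data: pd.DataFrame
    scale_state: str = RAW
    gene_map: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.scale_state not in (RAW, LOG10):
            raise AtlasError(f"unknown scale_state: {self.scale_state!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise AtlasError(f"duplicate row identifiers: {dups[:5]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise AtlasError(f"duplicate sample identifiers: {dups[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise AtlasError("atlas contains non-finite values")

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: pd.DataFrame, scale_state: str | None = None) -> "ExpressionAtlas":
        gene_map = None
        if self.gene_map is not None:
            gene_map = {p: g for p, g in self.gene_map.items() if p in data.index}
        return ExpressionAtlas(
            data=data,
            scale_state=self.scale_state if scale_state is None else scale_state,
            gene_map=gene_map,
        )

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="id")


def read_atlas(path: str | Path, fmt: str = "tsv", scale_state: str = RAW) -> ExpressionAtlas:
    """Read a genes × samples expression matrix from a TSV file.

    The first row is a header of sample identifiers; the first column holds
    gene/probe identifiers.  Non-numeric cells and ragged rows raise
    :class:`AtlasError` naming the offending line.
    """
    if fmt != "tsv":
        raise AtlasError(f"unsupported atlas format: {fmt!r}")
    path = Path(path)
    if not path.exists():
        raise AtlasError(f"atlas file does not exist: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header) - 1
        sample_ids = header[1:]
        ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols + 1:
                raise AtlasError(
                    f"{path}:{lineno}: expected {n_cols + 1} fields, found {len(parts)}"
                )
            ids.append(parts[0])
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise AtlasError(f"{path}:{lineno}: non-numeric expression value ({exc})") from None
    data = pd.DataFrame(rows, index=ids, columns=sample_ids, dtype=float)
    return ExpressionAtlas(data=data, scale_state=scale_state)


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column probe → gene TSV (no header required)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise AtlasError(f"{path}:{lineno}: expected two tab-separated columns")
            mapping[parts[0]] = parts[1]
    return mapping


def map_probes_to_genes(
    atlas: ExpressionAtlas,
    probe_map: Mapping[str, str],
    mode: str = "keep_probes_tag_gene",
) -> ExpressionAtlas:
    """Attach gene-model identifiers to probe rows, or collapse them.

    ``keep_probes_tag_gene`` keeps probe-level rows and records the probe →
    gene map, so network construction can later discard edges between probes
    of the same gene model.  ``average_collapse`` averages the rows of all
    probes mapping to one gene (the convention used for expression heatmaps).
    Probes absent from the map are dropped with a logged count.
    """
    if mode not in ("keep_probes_tag_gene", "average_collapse"):
        raise AtlasError(f"unknown probe mapping mode: {mode!r}")
    mapped = [p for p in atlas.data.index if p in probe_map]
    n_unmapped = atlas.n_genes - len(mapped)
    if not mapped:
        raise AtlasError("no atlas row identifiers found in the probe map")
    if n_unmapped:
        logger.warning("dropping %d probes absent from the probe map", n_unmapped)
    data = atlas.data.loc[mapped]
    if mode == "keep_probes_tag_gene":
        return ExpressionAtlas(
            data=data,
            scale_state=atlas.scale_state,
            gene_map={p: probe_map[p] for p in mapped},
        )
    genes = pd.Index([probe_map[p] for p in mapped], name="id")
    collapsed = data.groupby(genes, sort=False).mean()
    return ExpressionAtlas(data=collapsed, scale_state=atlas.scale_state)
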