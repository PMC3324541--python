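"""Neuron records: binary expression vectors plus LME phenotype labels.

Each neuron carries its cortical layer (L2/3–L6), morphological type
(large basket, Martinotti, nest basket, pyramidal) and electrical firing
type (continuous adapting / fast-spiking, delayed fast-spiking, continuous
stuttering), plus a 0/1 expression call per panel gene from single-cell
multiplex RT-PCR. Missing phenotype labels are represented explicitly (the
assay pipeline drops such neurons later, so missingness must survive I/O).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panel import GenePanel

__all__ = [
    "MISSING",
    "LAYERS",
    "MORPHOLOGIES",
    "ETYPES",
    "NeuronRecord",
    "FrequencyProfile",
    "read_expression_table",
    "write_expression_table",
    "expression_frequencies",
    "expression_matrix",
]

#: In-memory marker for an absent phenotype label (empty cell in files).
MISSING = "missing"

LAYERS = ("L2/3", "L4", "L5", "L6")
MORPHOLOGIES = ("LBC", "MC", "NBC", "PC")
ETYPES = ("cAD", "cFS", "dFS", "cST")

_LABEL_COLS = ("neuron_id", "Layer", "Morphology", "EType")


class FormatError(ValueError):
    """Malformed expression table (missing column, non-binary cell...)."""


@dataclass(frozen=True)
class NeuronRecord:
    neuron_id: str
    layer: str
    morphology: str
    etype: str
    expression: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.expression):
            raise ValueError("expression values must be 0/1")
        for value, allowed in (
            (self.layer, LAYERS),
            (self.morphology, MORPHOLOGIES),
            (self.etype, ETYPES),
        ):
            if value != MISSING and value not in allowed:
                raise ValueError(f"unknown label {value!r}")

    @property
    def complete(self) -> bool:
        """True when all three LME labels are present."""
        return MISSING not in (self.layer, self.morphology, self.etype)

    @property
    def lme(self) -> tuple[str, str, str]:
        return (self.layer, self.morphology, self.etype)

    def gene_value(self, panel: GenePanel, gene: str) -> int:
        return self.expression[panel.index(gene)]


@dataclass(frozen=True)
class FrequencyProfile:
    """Per-gene marginal expression frequencies and their mean.

    Also serves as the Bernoulli parameter vector for the random-data null
    model (each gene resampled independently at its observed frequency).
    """

    per_gene: dict[str, float]
    overall_mean: float

    def __getitem__(self, gene: str) -> float:
        return self.per_gene[gene]


def expression_matrix(records: Sequence[NeuronRecord]) -> np.ndarray:
    """(n_neurons, n_genes) 0/1 matrix in panel order."""
    return np.array([r.expression for r in records], dtype=np.int8)


def expression_frequencies(
    records: Sequence[NeuronRecord], panel: GenePanel
) -> FrequencyProfile:
    if not records:
        raise ValueError("need at least one record")
    mat = expression_matrix(records)
    if mat.shape[1] != len(panel):
        raise ValueError("record/panel length mismatch")
    freqs = mat.mean(axis=0)
    per_gene = {g: float(freqs[i]) for i, g in enumerate(panel)}
    return FrequencyProfile(per_gene=per_gene, overall_mean=float(freqs.mean()))


def _parse_label(cell) -> str:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return MISSING
    text = str(cell).strip()
    return text if text else MISSING


def read_expression_table(
    path: str | Path, panel: GenePanel, sep: str | None = None
) -> list[NeuronRecord]:
    """Read a delimited neurons × (labels + genes) table.

    The header must name ``neuron_id``, ``Layer``, ``Morphology``, ``EType``
    and every panel gene (canonical or ASCII alias). Blank label cells
    become :data:`MISSING`; expression cells must be exactly 0 or 1.
    With ``sep=None`` the delimiter is sniffed (comma or tab).
    """
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str,
                     keep_default_na=False, na_values=[])
    for col in _LABEL_COLS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    gene_cols: list[str] = []
    for g in panel:
        if g in df.columns:
            gene_cols.append(g)
        elif panel.ascii_name(g) in df.columns:
            gene_cols.append(panel.ascii_name(g))
        else:
            raise FormatError(f"missing required column for gene {g!r}")

    records: list[NeuronRecord] = []
    for row_idx, row in enumerate(df.itertuples(index=False)):
        row_map = dict(zip(df.columns, row))
        bits = []
        for col in gene_cols:
            cell = str(row_map[col]).strip()
            if cell not in ("0", "1"):
                raise FormatError(
                    f"non-binary expression value {cell!r} in column "
                    f"{col!r} at data row {row_idx}"
                )
            bits.append(int(cell))
        records.append(
            NeuronRecord(
                neuron_id=str(row_map["neuron_id"]).strip(),
                layer=_parse_label(row_map["Layer"]),
                morphology=_parse_label(row_map["Morphology"]),
                etype=_parse_label(row_map["EType"]),
                expression=tuple(bits),
            )
        )
    return records


def write_expression_table(
    records: Iterable[NeuronRecord],
    path: str | Path,
    panel: GenePanel,
    sep: str = ",",
) -> None:
    """Write records as CSV/TSV with ASCII gene headers; missing labels blank."""
    rows = []
    for r in records:
        row = {
            "neuron_id": r.neuron_id,
            "Layer": "" if r.layer == MISSING else r.layer,
            "Morphology": "" if r.morphology == MISSING else r.morphology,
            "EType": "" if r.etype == MISSING else r.etype,
        }
        row.update({panel.ascii_name(g): r.expression[i]
                    for i, g in enumerate(panel)})
        rows.append(row)
    cols = list(_LABEL_COLS) + list(panel.ascii_genes)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)
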