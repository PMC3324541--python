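"""Gene panel: ordered ion-channel gene symbols with ASCII aliases.

Single-cell multiplex RT-PCR panels in neocortical interneuron studies
screen a few dozen voltage-gated channel genes (Kv/HCN/SK/Ca families).
Several official-ish symbols carry Greek letters (Kvβ1, Caα1A); file headers
use ASCII aliases (Kvb1, Caa1A) so tables stay portable, while the Unicode
symbol remains the canonical display form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

__all__ = [
    "GenePanel",
    "default_panel",
    "full_panel",
    "panel_combination_count",
    "DEFAULT_GENES",
]

_GREEK_TO_ASCII = str.maketrans({"β": "b", "α": "a", "γ": "g"})

#: The 24 channel-subunit symbols screened in the neocortex panel this
#: package was built around (Kv: voltage-gated K+; HCN: hyperpolarization-
#: activated cation; SK: small-conductance Ca-activated K+; Caα/Caβ:
#: voltage-gated Ca2+ pore-forming and auxiliary subunits).
DEFAULT_GENES: tuple[str, ...] = (
    "Kv1.1", "Kv1.2", "Kv1.4", "Kv1.6", "Kvβ1", "Kvβ2",
    "Kv2.1", "Kv2.2", "Kv3.1", "Kv3.2", "Kv3.3", "Kv4.3",
    "HCN1", "HCN2", "HCN3", "HCN4", "SK2",
    "Caα1A", "Caα1B", "Caα1G", "Caα1I", "Caβ1", "Caβ3", "Caβ4",
)


def _ascii(symbol: str) -> str:
    return symbol.translate(_GREEK_TO_ASCII)


@dataclass(frozen=True)
class GenePanel:
    """Ordered, duplicate-free list of gene symbols.

    The order is load-bearing: it fixes feature-vector layout, truth-table
    literal order and every deterministic tie-break downstream.
    """

    genes: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        if len(genes) < 2:
            raise ValueError("panel needs at least 2 genes")
        if any(not g or not g.strip() for g in genes):
            raise ValueError("empty gene symbol in panel")
        index: dict[str, int] = {}
        for i, g in enumerate(genes):
            for key in {g, _ascii(g)}:
                if key in index:
                    raise ValueError(f"duplicate gene symbol {g!r}")
                index[key] = i
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def index(self, symbol: str) -> int:
        """Panel position of *symbol* (canonical or ASCII alias)."""
        try:
            return self._index[symbol]
        except KeyError:
            raise KeyError(f"gene {symbol!r} not in panel") from None

    def resolve(self, symbol: str) -> str:
        """Canonical symbol for *symbol*, accepting ASCII aliases."""
        return self.genes[self.index(symbol)]

    def ascii_name(self, symbol: str) -> str:
        """Portable ASCII header name for *symbol*."""
        return _ascii(self.resolve(symbol))

    @property
    def ascii_genes(self) -> tuple[str, ...]:
        return tuple(_ascii(g) for g in self.genes)

    def order_key(self, symbol: str):
        """Sort key: panel index for panel genes, then name for strangers."""
        if symbol in self._index:
            return (0, self.index(symbol), symbol)
        return (1, 0, symbol)

    # ---- persistence -----------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "GenePanel":
        """Load a panel: one symbol per line, or a JSON list of symbols."""
        text = Path(path).read_text(encoding="utf-8").strip()
        if text.startswith("["):
            return cls(tuple(json.loads(text)))
        lines = [ln.strip() for ln in text.splitlines()]
        return cls(tuple(ln for ln in lines if ln and not ln.startswith("#")))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.genes) + "\n", encoding="utf-8")


def default_panel() -> GenePanel:
    """The 24-gene neocortical ion-channel panel."""
    return GenePanel(DEFAULT_GENES)


def full_panel() -> GenePanel:
    """A 26-gene panel for full-scale simulations.

    Extends the default panel with two synthetic placeholder symbols
    (ICG25, ICG26) so simulations run at the full 26-gene assay width;
    supply your own panel file for fidelity to a specific assay.
    """
    return GenePanel(DEFAULT_GENES + ("ICG25", "ICG26"))


def panel_combination_count(panel_size: int) -> int:
    """Number of distinct non-empty gene subsets: 2**n - 1 (exact int).

    For a 26-gene panel this exceeds 67 million, which is why exhaustive
    combinatorial screening is replaced by greedy model search.
    """
    if panel_size < 1:
        raise ValueError("panel_size must be >= 1")
    return 2 ** int(panel_size) - 1
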