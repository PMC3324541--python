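"""Synthetic single-cell binary expression data with planted Boolean rules.

The generator emulates the structure of a single-cell multiplex RT-PCR
study of neocortical neurons: a fixed roster of LME groups with per-group
neuron counts (defaults reproduce the study layout of ten model groups with
counts 7,7,4,9,12,4,6,5,5,6 — 65 neurons — plus fourteen one-or-two-neuron
generalization groups, 18 neurons), sparse per-gene marginal expression
frequencies (drawn from [0.05, 0.5], matching panels whose mean frequency
is ~23% and maximum ~50%), and, in ``planted`` mode, target genes computed
from Boolean rules over other genes within designated neuron types.

Measurement noise is asymmetric: RT-PCR dropout produces false negatives
(1→0 flips at ``fn_rate``) while false positives are essentially absent; a
symmetric-noise flag exists for robustness studies only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data import NeuronRecord
from .logic import Formula, evaluate, parse_formula, variables
from .panel import GenePanel, default_panel

__all__ = ["PlantedRule", "SynthConfig", "MODEL_GROUP_COUNTS",
           "GENERALIZATION_GROUP_COUNTS", "generate", "table2_fixture",
           "config_from_mapping"]

LMEKey = tuple[str, str, str]


def _key(text: str) -> LMEKey:
    layer, rest = text.split(" ")
    morph, etype = rest.split("-")
    return (layer, morph, etype)


#: Model-set LME groups: ten types, 65 neurons, every count >= 4.
MODEL_GROUP_COUNTS: dict[LMEKey, int] = {
    _key("L2/3 LBC-cAD"): 7,
    _key("L2/3 LBC-cFS"): 7,
    _key("L2/3 LBC-dFS"): 4,
    _key("L2/3 MC-cAD"): 9,
    _key("L2/3 NBC-cFS"): 12,
    _key("L4 LBC-cST"): 4,
    _key("L4 MC-cAD"): 6,
    _key("L5 MC-cAD"): 5,
    _key("L5 PC-cAD"): 5,
    _key("L6 PC-cAD"): 6,
}

#: Generalization-set LME groups: fourteen new label combinations, 18 neurons.
GENERALIZATION_GROUP_COUNTS: dict[LMEKey, int] = {
    _key("L2/3 PC-cAD"): 2,
    _key("L2/3 NBC-cAD"): 1,
    _key("L2/3 LBC-cST"): 1,
    _key("L2/3 NBC-dFS"): 1,
    _key("L4 PC-cAD"): 1,
    _key("L4 LBC-dFS"): 1,
    _key("L4 LBC-cFS"): 2,
    _key("L4 NBC-cAD"): 1,
    _key("L4 NBC-dFS"): 1,
    _key("L5 NBC-cFS"): 2,
    _key("L5 LBC-dFS"): 1,
    _key("L5 LBC-cFS"): 2,
    _key("L5 MC-cFS"): 1,
    _key("L6 LBC-cST"): 1,
}


@dataclass(frozen=True)
class PlantedRule:
    """A Boolean dependency planted into the generated data.

    ``formula`` may be rule text (``"HCN3"``, ``"A AND NOT B"``) or a
    parsed formula; it applies within ``types`` (None = all groups).
    """

    target: str
    formula: Formula | str
    types: tuple[LMEKey, ...] | None = None

    def parsed(self) -> Formula:
        if isinstance(self.formula, str):
            return parse_formula(self.formula)
        return self.formula


@dataclass(frozen=True)
class SynthConfig:
    panel: GenePanel = field(default_factory=default_panel)
    group_counts: Mapping[LMEKey, int] = field(
        default_factory=lambda: dict(MODEL_GROUP_COUNTS))
    frequencies: Mapping[str, float] | None = None  # None: uniform [0.05,0.5]
    planted_rules: tuple[PlantedRule, ...] = ()
    fn_rate: float = 0.0
    symmetric_noise: bool = False
    mode: str = "bernoulli"  # "bernoulli" | "planted"
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("bernoulli", "planted"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 <= self.fn_rate <= 1.0):
            raise ValueError("fn_rate must be in [0, 1]")
        if any(n < 1 for n in self.group_counts.values()):
            raise ValueError("group counts must be >= 1")
        if self.frequencies is not None:
            for g, p in self.frequencies.items():
                if g not in self.panel:
                    raise ValueError(f"frequency for unknown gene {g!r}")
                if not (0.0 <= p <= 1.0):
                    raise ValueError("frequencies must be in [0, 1]")
        for rule in self.planted_rules:
            if rule.target not in self.panel:
                raise ValueError(f"rule target {rule.target!r} not in panel")
            for g in variables(rule.parsed()):
                if g not in self.panel:
                    raise ValueError(f"rule references unknown gene {g!r}")
            if self.panel.resolve(rule.target) in {
                    self.panel.resolve(g) for g in variables(rule.parsed())}:
                raise ValueError("rule target cannot be its own input")


def _frequency_vector(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    if config.frequencies is None:
        return rng.uniform(0.05, 0.5, size=len(config.panel))
    return np.array([config.frequencies.get(g, 0.23) for g in config.panel])


def generate(config: SynthConfig) -> list[NeuronRecord]:
    """Generate neuron records per the configuration, deterministically.

    In ``planted`` mode each rule target is overwritten by its formula's
    output within the applicable types (elsewhere it stays Bernoulli); the
    false-negative noise is applied to the whole matrix afterwards, so
    inputs and targets are corrupted alike — as RT-PCR dropout would.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    probs = _frequency_vector(config, rng)

    records: list[NeuronRecord] = []
    counter = 0
    rules = [] if config.mode == "bernoulli" else list(config.planted_rules)
    parsed = [(panel.resolve(r.target), r.parsed(), r.types) for r in rules]

    for key, count in config.group_counts.items():
        for _ in range(count):
            bits = (rng.random(len(panel)) < probs).astype(int)
            for target, formula, types in parsed:
                if types is not None and key not in types:
                    continue
                assignment = {g: int(bits[panel.index(g)])
                              for g in variables(formula)}
                bits[panel.index(target)] = int(evaluate(formula, assignment))
            # asymmetric assay noise: dropout flips 1 -> 0
            if config.fn_rate > 0:
                flip = rng.random(len(panel)) < config.fn_rate
                if config.symmetric_noise:
                    bits = np.where(flip, 1 - bits, bits)
                else:
                    bits = np.where(flip & (bits == 1), 0, bits)
            counter += 1
            records.append(NeuronRecord(
                neuron_id=f"n{counter:04d}",
                layer=key[0], morphology=key[1], etype=key[2],
                expression=tuple(int(b) for b in bits)))
    return records


def config_from_mapping(data: Mapping) -> SynthConfig:
    """Build a :class:`SynthConfig` from a plain mapping (JSON/YAML).

    Recognized keys: ``panel`` (list of symbols), ``group_counts`` (list of
    ``[layer, morphology, etype, count]``), ``frequencies`` (gene → p),
    ``planted_rules`` (list of ``{"target", "formula", "types"?}``),
    ``fn_rate``, ``symmetric_noise``, ``mode``, ``seed``.
    """
    kwargs: dict = {}
    if "panel" in data:
        kwargs["panel"] = GenePanel(tuple(data["panel"]))
    if "group_counts" in data:
        kwargs["group_counts"] = {
            (l, m, e): int(n) for l, m, e, n in data["group_counts"]}
    if "frequencies" in data:
        kwargs["frequencies"] = {g: float(p)
                                 for g, p in data["frequencies"].items()}
    if "planted_rules" in data:
        kwargs["planted_rules"] = tuple(
            PlantedRule(
                target=r["target"], formula=r["formula"],
                types=tuple(tuple(t) for t in r["types"])
                if r.get("types") else None)
            for r in data["planted_rules"])
    for key in ("fn_rate", "symmetric_noise", "mode", "seed"):
        if key in data:
            kwargs[key] = data[key]
    config = SynthConfig(**kwargs)
    config.validate()
    return config


def table2_fixture(seed: int = 0, **overrides) -> list[NeuronRecord]:
    """Records instantiating the full study layout: 10 model LME groups
    (65 neurons) plus 14 generalization groups (18 neurons), expression
    filled per the configured mode (Bernoulli by default)."""
    counts = dict(MODEL_GROUP_COUNTS)
    counts.update(GENERALIZATION_GROUP_COUNTS)
    config = SynthConfig(group_counts=counts, seed=seed, **overrides)
    return generate(config)
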