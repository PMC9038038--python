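"""Phase I/II biotransformation rules and expected-product enumeration.

A transformation rule is a named elemental gain/loss (hydroxylation = +O,
N-desisopropylation = -C3H6, glucuronidation = +C6H8O6, ...).  Applying chains
of rules to a parent compound's formula enumerates the neutral monoisotopic
masses of its expected biotransformation products (bioTPs), which are then
ppm-matched against non-target LC-HRMS feature tables.

Rules compose: ``enumerate_biotps`` walks every feasible rule chain up to a
depth limit, deduplicates products by elemental formula (distinct routes to
the same formula are kept as alternative chain annotations), and never emits
the parent itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import yaml

from .chemformula import FormulaError, MolecularFormula, monoisotopic_mass, parse_formula

__all__ = [
    "TransformationRule",
    "PredictedBioTP",
    "InfeasibleTransformation",
    "apply_rule",
    "apply_chain",
    "enumerate_biotps",
    "default_rule_set",
    "load_rules",
    "rules_by_name",
]


class InfeasibleTransformation(ValueError):
    """A rule application would drive an element count negative."""


@dataclass(frozen=True)
class TransformationRule:
    """A named elemental delta, e.g. hydroxylation (+O), phase I or II."""

    name: str
    phase: str  # "I" or "II"
    gain: MolecularFormula = field(default_factory=MolecularFormula)
    loss: MolecularFormula = field(default_factory=MolecularFormula)

    def __post_init__(self) -> None:
        if self.phase not in ("I", "II"):
            raise ValueError(f"phase must be 'I' or 'II', got {self.phase!r}")
        if not self.delta:
            raise ValueError(f"rule {self.name!r} has a zero delta")

    @property
    def delta(self) -> MolecularFormula:
        return self.gain - self.loss

    @classmethod
    def from_strings(
        cls, name: str, phase: str, gain: str = "", loss: str = ""
    ) -> "TransformationRule":
        return cls(
            name=name,
            phase=phase,
            gain=parse_formula(gain) if gain else MolecularFormula(),
            loss=parse_formula(loss) if loss else MolecularFormula(),
        )


@dataclass(frozen=True)
class PredictedBioTP:
    """An expected bioTP: product formula, neutral mass, and every distinct
    rule chain that produces it (isomeric-route degeneracy)."""

    product_formula: MolecularFormula
    neutral_mass: float
    rule_chains: tuple[tuple[str, ...], ...]

    @property
    def n_steps(self) -> int:
        return min(len(c) for c in self.rule_chains)

    @property
    def rule_chain(self) -> tuple[str, ...]:
        """Shortest (first in deterministic order) route."""
        return min(self.rule_chains, key=lambda c: (len(c), c))

    def __str__(self) -> str:
        return f"{self.product_formula} ({'+'.join(self.rule_chain)})"


def apply_rule(
    parent: MolecularFormula, rule: TransformationRule
) -> MolecularFormula:
    """Apply one rule to a finalized parent formula; error if any element
    count would go negative."""
    if not parent.is_finalized:
        raise FormulaError("parent formula is not finalized")
    product = parent + rule.delta
    negative = sorted(el for el, n in product if n < 0)
    if negative:
        raise InfeasibleTransformation(
            f"rule {rule.name!r} on {parent} leaves negative count "
            f"for {', '.join(negative)}"
        )
    return product


def apply_chain(
    parent: MolecularFormula, chain: Sequence[TransformationRule]
) -> MolecularFormula:
    current = parent
    for rule in chain:
        current = apply_rule(current, rule)
    return current


def enumerate_biotps(
    parent: MolecularFormula,
    rules: Sequence[TransformationRule],
    max_steps: int,
    *,
    max_phase2: int | None = None,
    phase2_terminal: bool = False,
) -> list[PredictedBioTP]:
    """Every distinct product formula reachable by <= ``max_steps`` feasible
    rule applications (rules may repeat).

    Products are deduplicated by formula with all distinct rule chains
    retained, sorted by (neutral mass, Hill string).  The parent formula is
    suppressed even if a chain nets to a zero delta.

    ``max_phase2`` caps the number of phase II (conjugation) steps per chain;
    ``phase2_terminal`` additionally forbids any step after a phase II one —
    conjugates are typically terminal metabolites.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if not rules:
        raise ValueError("rule list is empty")

    products: dict[str, tuple[MolecularFormula, set[tuple[str, ...]]]] = {}
    frontier: list[tuple[MolecularFormula, tuple[str, ...], int]] = [
        (parent, (), 0)
    ]
    for _ in range(max_steps):
        next_frontier = []
        for formula, chain, n_p2 in frontier:
            if phase2_terminal and n_p2 > 0:
                continue
            for rule in rules:
                if rule.phase == "II":
                    if max_phase2 is not None and n_p2 >= max_phase2:
                        continue
                try:
                    product = apply_rule(formula, rule)
                except InfeasibleTransformation:
                    continue
                new_chain = chain + (rule.name,)
                if product.counts != parent.counts:
                    key = product.hill()
                    if key not in products:
                        products[key] = (product, set())
                    products[key][1].add(new_chain)
                next_frontier.append(
                    (product, new_chain, n_p2 + (rule.phase == "II"))
                )
        frontier = next_frontier

    out = [
        PredictedBioTP(
            product_formula=formula,
            neutral_mass=monoisotopic_mass(formula),
            rule_chains=tuple(sorted(chains, key=lambda c: (len(c), c))),
        )
        for formula, chains in products.values()
    ]
    out.sort(key=lambda p: (p.neutral_mass, p.product_formula.hill()))
    return out


# Default rule set, curated from the propranolol bioTPs this workflow was
# designed to recover: hydroxylation, N-dealkylation, desaturation/reduction,
# hydration, oxidative O-dearylation (loss of the naphthalene moiety), and the
# phase II conjugations glucuronidation and sulfation.  User-overridable via
# a YAML rule file (see load_rules).
_DEFAULT_RULES: tuple[tuple[str, str, str, str], ...] = (
    # (name, phase, gain, loss)
    ("hydroxylation", "I", "O", ""),
    ("desisopropylation", "I", "", "C3H6"),
    ("desaturation", "I", "", "H2"),
    ("reduction", "I", "H2", ""),
    ("hydration", "I", "H2O", ""),
    ("o_dearylation", "I", "", "C10H6"),
    ("glucuronidation", "II", "C6H8O6", ""),
    ("sulfation", "II", "SO3", ""),
)

#: Default chain-depth for enumeration and phase II constraints used by the
#: pipeline: depth 2, at most one conjugation per chain, conjugation terminal.
DEFAULT_MAX_STEPS = 2
DEFAULT_MAX_PHASE2 = 1
DEFAULT_PHASE2_TERMINAL = True


def default_rule_set() -> list[TransformationRule]:
    """The documented default phase I + II rule set (see module docstring)."""
    return [
        TransformationRule.from_strings(name, phase, gain, loss)
        for name, phase, gain, loss in _DEFAULT_RULES
    ]


def rules_by_name(rules: Iterable[TransformationRule]) -> dict[str, TransformationRule]:
    return {r.name: r for r in rules}


def load_rules(path) -> list[TransformationRule]:
    """Load a rule set from YAML: a list of mappings with keys
    ``name``, ``phase`` and ``gain`` and/or ``loss`` (Hill-notation strings).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not raw:
        raise ValueError(f"rule file {path} must contain a nonempty list")
    rules = []
    for i, entry in enumerate(raw):
        try:
            rules.append(
                TransformationRule.from_strings(
                    entry["name"],
                    str(entry["phase"]),
                    entry.get("gain", "") or "",
                    entry.get("loss", "") or "",
                )
            )
        except (KeyError, ValueError, FormulaError) as exc:
            raise ValueError(f"bad rule entry #{i} in {path}: {exc}") from exc
    return rules


def save_rules(rules: Sequence[TransformationRule], path) -> None:
    doc = [
        {
            "name": r.name,
            "phase": r.phase,
            "gain": r.gain.hill() if r.gain else "",
            "loss": r.loss.hill() if r.loss else "",
        }
        for r in rules
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
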