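"""Metacluster rule sets: the supervised stage of the phenotyper as data.

A :class:`RuleSet` is an *ordered* list of :class:`MetaRule` plus a fallback
label.  A rule matches a cell iff

* the cell's dominant lineage marker equals the rule's (or the rule accepts
  any lineage), and
* every threshold condition on scaled expression holds, and
* none of the rule's ``topk_exclude`` markers appears in the cell's top-k
  ranked markers, and
* at least one ``topk_require`` marker appears in the top-k (if the set is
  non-empty).

Evaluation is first-match-wins; cells matching no rule receive the fallback
label (negative selection -- e.g. hepatocytes in a liver panel that has no
hepatocyte marker).  Multiple rules may share a label (e.g. macrophages via
CD68 or via CD163).

Default configurations for a human liver panel (10 lineage markers ->
10 metacluster labels including the fallback) and a mouse liver panel
(16 lineage markers; 7 immune metaclusters) ship as editable JSON under
``imcpheno/data`` and load via :func:`human_rules` / :func:`mouse_rules`.
"""

from __future__ import annotations

import json
import operator
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError

COMPARATORS = {
    ">": operator.gt,
    ">=": operator.ge,
    "<": operator.lt,
    "<=": operator.le,
}


@dataclass(frozen=True)
class MetaRule:
    label: str
    lineage_marker: str | None  # None = any lineage
    conditions: tuple[tuple[str, str, float], ...] = ()
    topk_exclude: frozenset[str] = frozenset()
    topk_require: frozenset[str] = frozenset()
    rank_k: int | None = None  # overrides the rule set's global k
    immune: bool = False

    def __post_init__(self) -> None:
        if not self.label:
            raise ConfigurationError("rule label must be non-empty")
        for marker, cmp, _ in self.conditions:
            if cmp not in COMPARATORS:
                raise ConfigurationError(
                    f"rule {self.label!r}: unknown comparator {cmp!r}"
                )

    def referenced_markers(self) -> set[str]:
        markers = set(self.topk_exclude) | set(self.topk_require)
        markers.update(m for m, _, _ in self.conditions)
        if self.lineage_marker is not None:
            markers.add(self.lineage_marker)
        return markers


@dataclass
class RuleSet:
    name: str
    lineage_markers: list[str]
    rules: list[MetaRule]
    fallback_label: str
    fallback_immune: bool = False
    rank_k: int = 3
    species: str = ""
    conflict_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.fallback_label:
            raise ConfigurationError("fallback label must be defined")
        if not self.lineage_markers:
            raise ConfigurationError("lineage marker list must be non-empty")

    @property
    def labels(self) -> list[str]:
        """Distinct metacluster labels in rule order, fallback last."""
        seen: list[str] = []
        for rule in self.rules:
            if rule.label not in seen:
                seen.append(rule.label)
        if self.fallback_label not in seen:
            seen.append(self.fallback_label)
        return seen

    @property
    def immune_labels(self) -> list[str]:
        seen: list[str] = []
        for rule in self.rules:
            if rule.immune and rule.label not in seen:
                seen.append(rule.label)
        if self.fallback_immune and self.fallback_label not in seen:
            seen.append(self.fallback_label)
        return seen

    def validate(self, panel_markers: list[str]) -> None:
        """Raise ConfigurationError if any rule references an unknown marker."""
        panel = set(panel_markers)
        missing_lineage = [m for m in self.lineage_markers if m not in panel]
        if missing_lineage:
            raise ConfigurationError(
                f"lineage markers not in panel: {missing_lineage}"
            )
        for rule in self.rules:
            unknown = rule.referenced_markers() - panel
            if unknown:
                raise ConfigurationError(
                    f"rule {rule.label!r} references unknown markers: {sorted(unknown)}"
                )

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "species": self.species,
            "lineage_markers": list(self.lineage_markers),
            "fallback_label": self.fallback_label,
            "fallback_immune": self.fallback_immune,
            "rank_k": self.rank_k,
            "conflict_pairs": [list(p) for p in self.conflict_pairs],
            "rules": [
                {
                    "label": r.label,
                    "lineage_marker": r.lineage_marker,
                    "conditions": [list(c) for c in r.conditions],
                    "topk_exclude": sorted(r.topk_exclude),
                    "topk_require": sorted(r.topk_require),
                    "rank_k": r.rank_k,
                    "immune": r.immune,
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RuleSet":
        try:
            rules = [
                MetaRule(
                    label=r["label"],
                    lineage_marker=r.get("lineage_marker"),
                    conditions=tuple(
                        (m, cmp, float(t)) for m, cmp, t in r.get("conditions", [])
                    ),
                    topk_exclude=frozenset(r.get("topk_exclude", [])),
                    topk_require=frozenset(r.get("topk_require", [])),
                    rank_k=r.get("rank_k"),
                    immune=bool(r.get("immune", False)),
                )
                for r in data["rules"]
            ]
            return cls(
                name=data["name"],
                species=data.get("species", ""),
                lineage_markers=list(data["lineage_markers"]),
                rules=rules,
                fallback_label=data["fallback_label"],
                fallback_immune=bool(data.get("fallback_immune", False)),
                rank_k=int(data.get("rank_k", 3)),
                conflict_pairs=[tuple(p) for p in data.get("conflict_pairs", [])],
            )
        except KeyError as exc:
            raise ConfigurationError(f"rule set missing key: {exc}") from exc

    @classmethod
    def load(cls, path: str | Path) -> "RuleSet":
        path = Path(path)
        with open(path) as fh:
            if path.suffix.lower() in (".yaml", ".yml"):
                data = yaml.safe_load(fh)
            else:
                data = json.load(fh)
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def _packaged(name: str) -> RuleSet:
    text = resources.files("imcpheno.data").joinpath(name).read_text()
    return RuleSet.from_dict(json.loads(text))


def human_rules() -> RuleSet:
    """Default human liver rule tree (editable copy in imcpheno/data)."""
    return _packaged("human_rules.json")


def mouse_rules() -> RuleSet:
    """Default mouse liver rule tree (editable copy in imcpheno/data)."""
    return _packaged("mouse_rules.json")
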