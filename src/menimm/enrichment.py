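"""Offline gene-set over-representation analysis.

A stand-alone hypergeometric test of module genes against user-supplied GMT
gene-set collections, with Bonferroni correction across the tested sets.
The universe defaults to the genes actually analysed (the merged expression
matrix), which is the testable background for a module drawn from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from scipy.stats import hypergeom

from .errors import ValidationError


@dataclass
class GeneSet:
    name: str
    description: str
    members: frozenset[str]


def read_gmt(path) -> dict[str, GeneSet]:
    """Parse a GMT file: ``name<TAB>description<TAB>gene...`` per line.

    Duplicate members within a set are de-duplicated with a warning;
    duplicate set names or lines with fewer than 3 fields are errors.
    """
    sets: dict[str, GeneSet] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(f"{path}: line {lineno} has fewer than 3 fields")
        name, desc, members = fields[0], fields[1], [g for g in fields[2:] if g]
        if not members:
            raise ValidationError(f"{path}: line {lineno}: set {name!r} has no members")
        if name in sets:
            raise ValidationError(f"{path}: duplicate set name {name!r} at line {lineno}")
        if len(set(members)) < len(members):
            warnings.warn(f"{path}: line {lineno}: duplicate members in {name!r} de-duplicated")
        sets[name] = GeneSet(name, desc, frozenset(members))
    return sets


def write_gmt(sets: dict[str, GeneSet], path) -> None:
    lines = ["\t".join([s.name, s.description, *sorted(s.members)]) for s in sets.values()]
    Path(path).write_text("\n".join(lines) + "\n")


def overrepresentation(module_genes, universe, sets: dict[str, GeneSet]) -> list[dict]:
    """Hypergeometric upper-tail over-representation of a module in each set.

    ``p = P(X >= overlap)`` for X hypergeometric with population = universe,
    successes = set intersected with universe, draws = module size;
    ``bonferroni_p = min(1, p * number of tested sets)``.  Rows are sorted
    by p ascending (ties by set name).
    """
    module = set(module_genes)
    universe = set(universe)
    outside = sorted(module - universe)
    if outside:
        raise ValidationError(f"module genes outside the universe: {outside[:10]}")
    N, n_draw = len(universe), len(module)
    rows = []
    for s in sets.values():
        members = s.members & universe
        k = len(module & members)
        K = len(members)
        p = float(hypergeom.sf(k - 1, N, K, n_draw)) if K else 1.0
        rows.append({
            "set_name": s.name, "overlap": k, "module_size": n_draw,
            "set_size": K, "universe_size": N, "p": min(p, 1.0),
        })
    m = len(rows)
    for r in rows:
        r["bonferroni_p"] = min(1.0, r["p"] * m)
    rows.sort(key=lambda r: (r["p"], r["set_name"]))
    return rows
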