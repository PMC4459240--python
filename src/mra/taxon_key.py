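"""Dichotomous identification key with quantitative couplets.

The key walks two-branch couplets whose conditions are thresholds on body
ratios; optional observer-supplied qualitative traits (booleans such as
"gena_carinate") resolve a couplet only when the quantitative conditions are
ambiguous — when a ratio falls in the gap between the two branches' printed
ranges the classification is "indeterminate" rather than a guess.  The key
definition and the per-species diagnosis ranges ship as a plain-text YAML
resource so every threshold is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

__all__ = [
    "KeyResult",
    "load_key",
    "compute_ratios",
    "key_classify",
    "diagnosis_check",
    "SPECIES",
]

SPECIES = (
    "A. apiovorus", "A. calandrae", "A. caryedophagus",
    "A. ceylonensis", "A. cornis", "A. quinarius",
)


@dataclass
class KeyResult:
    """Outcome of a key walk: species label or "indeterminate" plus trace."""

    label: str
    trace: list[tuple[int, str]] = field(default_factory=list)
    unmet: list[str] = field(default_factory=list)


def load_key() -> dict:
    """Load the shipped key definition (couplets, ratios, diagnoses)."""
    text = (resources.files("mra") / "data" / "anisopteromalus_key.yaml").read_text()
    return yaml.safe_load(text)


_KEY = None


def _key() -> dict:
    global _KEY
    if _KEY is None:
        _KEY = load_key()
    return _KEY


def compute_ratios(measurements) -> dict[str, float]:
    """Compute every ratio referenced by the key and diagnoses.

    *measurements* maps character abbreviations to µm values (a dict or a
    pandas Series).  Raises ``KeyError`` naming the first character that is
    required but absent.
    """
    meas = dict(measurements)
    out: dict[str, float] = {}
    for name in _key()["ratios"]:
        num, den = name.split(":")
        for ch in (num, den):
            if ch not in meas or pd.isna(meas[ch]):
                raise KeyError(f"missing character {ch!r} needed for ratio {name!r}")
        out[name] = float(meas[num]) / float(meas[den])
    return out


def _condition_holds(cond: dict, ratios: dict[str, float]) -> bool:
    val = ratios[cond["ratio"]]
    op = cond["op"]
    if op == "within":
        lo, hi = cond["bounds"]
        return lo <= val <= hi
    bound = cond["bound"]
    return {"<": val < bound, "<=": val <= bound,
            ">": val > bound, ">=": val >= bound}[op]


def _branch_quant(branch: dict, ratios: dict[str, float]) -> bool:
    results = [_condition_holds(c, ratios) for c in branch["conditions"]]
    return all(results) if branch.get("combine", "and") == "and" else any(results)


def _describe(branch: dict) -> str:
    parts = []
    for c in branch["conditions"]:
        if c["op"] == "within":
            parts.append(f"{c['ratio']} in [{c['bounds'][0]}, {c['bounds'][1]}]")
        else:
            parts.append(f"{c['ratio']} {c['op']} {c['bound']}")
    return f" {branch.get('combine', 'and')} ".join(parts)


def key_classify(ratios: dict[str, float],
                 qualitative_traits: dict[str, bool] | None = None) -> KeyResult:
    """Walk the key from couplet 1 and classify a specimen.

    Quantitative thresholds decide each couplet.  When neither (or both)
    branches' conditions hold — e.g. a ratio falls in the gap between the two
    printed ranges — a supplied qualitative trait may resolve the couplet;
    otherwise the result is "indeterminate" with the ambiguous thresholds
    listed in ``unmet``.  Traits supporting both branches at once raise
    ``ValueError``.
    """
    traits = qualitative_traits or {}
    couplets = _key()["couplets"]
    trace: list[tuple[int, str]] = []
    unmet: list[str] = []
    node: int | str = 1
    while isinstance(node, int):
        cpl = couplets[node]
        qa = _branch_quant(cpl["a"], ratios)
        qb = _branch_quant(cpl["b"], ratios)
        branch_name = None
        if qa != qb:
            branch_name = "a" if qa else "b"
        else:
            # ambiguous: try qualitative traits (each supplied trait votes
            # for the branch whose requirement it matches)
            support = {}
            for bn in ("a", "b"):
                req = cpl[bn].get("traits", {})
                support[bn] = any(t in req and req[t] == v
                                  for t, v in traits.items())
            if support["a"] and support["b"]:
                raise ValueError(f"contradictory qualitative traits at couplet {node}")
            if support["a"] or support["b"]:
                branch_name = "a" if support["a"] else "b"
            else:
                unmet.append(
                    f"couplet {node}: neither branch decided "
                    f"(a: {_describe(cpl['a'])}; b: {_describe(cpl['b'])})"
                    if not qa else
                    f"couplet {node}: both branches hold "
                    f"(a: {_describe(cpl['a'])}; b: {_describe(cpl['b'])})")
                trace.append((node, "?"))
                return KeyResult("indeterminate", trace, unmet)
        trace.append((node, branch_name))
        node = cpl[branch_name]["outcome"]
    return KeyResult(str(node), trace, unmet)


def diagnosis_check(ratios: dict[str, float], species: str,
                    ranges: dict[str, tuple[float, float]] | None = None) -> pd.DataFrame:
    """Check a specimen's ratios against a species' diagnostic ranges.

    *species* must be one of the species with printed full diagnoses
    (A. calandrae, A. cornis, A. quinarius) unless *ranges* supplies the
    ranges explicitly.  Returns a table with one row per diagnostic ratio:
    value, low, high and whether the value lies inside.
    """
    if not ratios:
        raise ValueError("empty ratio set")
    if ranges is None:
        diagnoses = _key()["diagnoses"]
        if species not in diagnoses:
            raise KeyError(
                f"no shipped diagnosis for {species!r}; supply ranges=")
        ranges = {k: tuple(v) for k, v in diagnoses[species].items()}
    rows = []
    for name, (lo, hi) in ranges.items():
        if name not in ratios:
            raise KeyError(f"ratio {name!r} not supplied")
        val = ratios[name]
        rows.append({"ratio": name, "value": val, "low": lo, "high": hi,
                     "inside": bool(lo <= val <= hi)})
    return pd.DataFrame(rows).set_index("ratio")


def classify_table(table, qualitative_traits=None) -> pd.DataFrame:
    """Classify every specimen of a measurement table with the key.

    Returns a DataFrame indexed by specimen with the assigned label and the
    couplet trace; specimens lacking a required character get label "error".
    """
    rows = []
    for sid in table.specimen_ids:
        meas = table.values.loc[sid]
        try:
            ratios = compute_ratios(meas)
            res = key_classify(ratios, qualitative_traits)
            rows.append({"specimen_id": sid, "label": res.label,
                         "trace": ";".join(f"{c}{b}" for c, b in res.trace),
                         "unmet": " | ".join(res.unmet)})
        except KeyError as exc:
            rows.append({"specimen_id": sid, "label": "error",
                         "trace": "", "unmet": str(exc)})
    return pd.DataFrame(rows).set_index("specimen_id")
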