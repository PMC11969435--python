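"""Per-system summaries, comparative percent-change arithmetic and renderers.

System names follow the coated-nanosystem grammar ``NP^a-nPEG_b-X``:
core material (ND, TiO2, ...), core diameter a (nm), chain count n, PEG
molecular weight b (Da) and solution-side terminal group X (OH or CH3).
Two-particle boxes carry a leading ``2`` and a ``^far``/``^close`` suffix.

Percent changes are rounded half away from zero to the nearest integer
percent; energy comparisons may be taken on magnitudes (the sign of an
attractive energy is not part of a "doubling" statement), and both choices
are explicit in the comparison plan schema.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

_NAME_RE = re.compile(
    r"^(?P<count>2)?"
    r"(?P<core>[A-Za-z][A-Za-z0-9]*?)"
    r"\^(?P<diameter>\d+)-"
    r"(?P<n_chains>\d+)PEG_(?P<peg_mw>\d+)"
    r"[-–](?P<terminal>OH|CH3)"
    r"(?:\^(?P<config>far|close))?$"
)


def parse_system_name(name: str) -> dict:
    """Parse a coated-nanosystem name into its structured fields.

    >>> parse_system_name("ND^2-50PEG_500-OH")["n_chains"]
    50
    """
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(
            f"malformed system name {name!r}; expected NP^a-nPEG_b-X with "
            "a = diameter (nm), n = chain count, b = PEG MW (Da), "
            "X in {OH, CH3} (optionally 2...^far/^close for two-particle boxes)"
        )
    d = m.groupdict()
    return {
        "core": d["core"],
        "diameter_nm": int(d["diameter"]),
        "n_chains": int(d["n_chains"]),
        "peg_mw": int(d["peg_mw"]),
        "terminal": d["terminal"],
        "n_particles": 2 if d["count"] else 1,
        "configuration": d["config"],
    }


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def percent_change(reference: float, other: float) -> int:
    """Signed integer percent change of ``other`` relative to ``reference``,
    rounded half away from zero.  Positive = increase."""
    if reference == 0:
        raise ValueError("percent change undefined for zero reference")
    return _round_half_away(100.0 * (other - reference) / reference)


def per_chain_normalize(energy: float, n_chains: int) -> float:
    """Energy per grafted chain (kcal·mol⁻¹·chain⁻¹)."""
    if n_chains <= 0:
        raise ValueError("chain count must be > 0")
    return energy / n_chains


@dataclass
class Comparison:
    """One comparative statement: quantity, system pair, rounded percent."""

    quantity: str
    reference: str
    other: str
    percent: int  # positive magnitude
    direction: str  # "increase" | "decrease" | "none"


@dataclass
class SystemSummary:
    """Named bundle of per-system scalar results.

    ``quantities`` maps short names (Rg, h, d, thk, E_peg_peg, ...) to
    values in package units; reporting-unit conversions happen in renderers.
    """

    name: str
    quantities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.parsed = parse_system_name(self.name)

    def __getitem__(self, key: str) -> float:
        return self.quantities[key]

    def __contains__(self, key: str) -> bool:
        return key in self.quantities


def compare_systems(
    summaries: dict[str, dict[str, float]],
    plan: list[dict],
) -> tuple[list[Comparison], pd.DataFrame]:
    """Deterministic table of rounded percent changes between system pairs.

    Each plan row needs ``quantity``, ``reference`` and ``other`` (system
    names); optional ``magnitude`` (compare |values|) and ``per_chain``
    (normalize by the summary's ``n_chains`` first).  Rows whose quantity is
    missing in either summary are skipped with a warning.
    """
    rows: list[Comparison] = []
    for item in plan:
        q = item["quantity"]
        ref_name, oth_name = item["reference"], item["other"]
        try:
            ref_s, oth_s = summaries[ref_name], summaries[oth_name]
        except KeyError as exc:
            warnings.warn(f"unknown system {exc} in plan; row skipped", stacklevel=2)
            continue
        if q not in ref_s or q not in oth_s:
            warnings.warn(
                f"quantity {q!r} missing for {ref_name} or {oth_name}; row skipped",
                stacklevel=2,
            )
            continue
        ref_v, oth_v = float(ref_s[q]), float(oth_s[q])
        if item.get("per_chain"):
            ref_v = per_chain_normalize(ref_v, int(ref_s["n_chains"]))
            oth_v = per_chain_normalize(oth_v, int(oth_s["n_chains"]))
        if item.get("magnitude"):
            ref_v, oth_v = abs(ref_v), abs(oth_v)
        signed = percent_change(ref_v, oth_v)
        direction = "increase" if signed > 0 else "decrease" if signed < 0 else "none"
        rows.append(Comparison(q, ref_name, oth_name, abs(signed), direction))
    df = pd.DataFrame(
        [
            {
                "quantity": c.quantity,
                "reference": c.reference,
                "other": c.other,
                "percent": c.percent,
                "direction": c.direction,
            }
            for c in rows
        ]
    )
    return rows, df


def render_comparisons(df: pd.DataFrame, fmt: str = "markdown") -> str:
    """Render a comparison table as csv, json or markdown."""
    if fmt == "csv":
        return df.to_csv(index=False)
    if fmt == "json":
        return df.to_json(orient="records", indent=2)
    if fmt == "markdown":
        return df.to_markdown(index=False)
    raise ValueError(f"unknown format {fmt!r}")
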