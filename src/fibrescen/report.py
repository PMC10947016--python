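"""Fixed-width text rendering of the population summary table."""

from __future__ import annotations

from .population import SummaryRow, SummaryTable

__all__ = ["render_summary"]


def _cell(mean: float, se: float) -> str:
    return f"{mean:.1f} ({se:.1f})"


def _row_line(row: SummaryRow, width: int) -> str:
    label = f"  {row.group_label}".ljust(width)
    if row.current is None or row.scenario is None:
        return f"{label}{row.n:>6}  " + "  ".join("-".center(12) for _ in range(4))
    cells = [
        _cell(row.current.mean_g_per_day, row.current.se_mean),
        _cell(row.scenario.mean_g_per_day, row.scenario.se_mean),
        _cell(row.current.pct_reaching, row.current.se_pct),
        _cell(row.scenario.pct_reaching, row.scenario.se_pct),
    ]
    return f"{label}{row.n:>6}  " + "  ".join(c.rjust(12) for c in cells)


def render_summary(table: SummaryTable, scenario_name: str = "Higher fibre") -> str:
    """Render mean (SE) intake and % reaching the recommendation, 1-decimal.

    Layout mirrors the conventional survey presentation: a Gender section
    and an Age section, with paired current/scenario columns for intake and
    for the percentage above the recommended intake.
    """
    width = max(len(f"  {r.group_label}") for r in table.rows) + 2
    header1 = (
        " " * (width + 6 + 2)
        + "Fibre intake (g/day)".center(26)
        + "  "
        + "Above recommended (%)".center(26)
    )
    header2 = (
        "".ljust(width)
        + "n".rjust(6)
        + "  "
        + "  ".join(
            c.rjust(12)
            for c in ("Current", scenario_name, "Current", scenario_name)
        )
    )
    lines = [header1, header2, "-" * len(header2)]
    lines.append("Gender")
    lines.extend(_row_line(r, width) for r in table.sex_rows)
    lines.append("Age")
    lines.extend(_row_line(r, width) for r in table.age_rows)
    return "\n".join(lines) + "\n"
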