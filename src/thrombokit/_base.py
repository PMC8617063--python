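"""Shared result-object plumbing: summary tables and a common base."""

from __future__ import annotations

import math


class FitResultsBase:
    """Base for fitted-model result objects.

    Concrete results expose their estimates as attributes and implement
    ``summary()`` returning a plain-text table.
    """

    def summary(self) -> str:  # pragma: no cover - overridden
        raise NotImplementedError

    def __repr__(self) -> str:
        return f"<{type(self).__name__}>"


def _fmt(x: float) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "nan"
    a = abs(x)
    if a != 0 and (a < 1e-3 or a >= 1e5):
        return f"{x:.4e}"
    return f"{x:.4g}"


def summary_table(title: str, param_rows, extra_rows=()) -> str:
    """Render a statsmodels-flavoured fixed-width summary table.

    ``param_rows`` are (name, estimate, std. err.) triples; ``extra_rows``
    are (name, string) diagnostics appended below.
    """
    width = 64
    lines = [title.center(width), "=" * width]
    lines.append(f"{'parameter':<34}{'estimate':>14}{'std err':>14}")
    lines.append("-" * width)
    for name, est, se in param_rows:
        lines.append(f"{name:<34}{_fmt(est):>14}{_fmt(se):>14}")
    if extra_rows:
        lines.append("-" * width)
        for name, val in extra_rows:
            lines.append(f"{name:<34}{val:>28}")
    lines.append("=" * width)
    return "\n".join(lines)
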