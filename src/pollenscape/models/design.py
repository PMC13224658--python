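"""Minimal term language for design matrices.

Terms are strings over the data columns: a main effect ``"x"``, a quadratic
``"I(x^2)"`` and a two-way interaction ``"a:b"``.  Marginality helpers map a
term to the main effects it requires.
"""

from __future__ import annotations

import numpy as np

__all__ = ["parse_term", "design_matrix", "required_mains", "term_metrics"]


def parse_term(term: str, df) -> np.ndarray:
    if term.startswith("I(") and term.endswith("^2)"):
        base = term[2:-3]
        return np.asarray(df[base], dtype=float) ** 2
    if ":" in term:
        a, b = term.split(":", 1)
        return np.asarray(df[a], dtype=float) * np.asarray(df[b], dtype=float)
    return np.asarray(df[term], dtype=float)


def design_matrix(df, terms) -> np.ndarray:
    """Intercept column followed by one column per term, in order."""
    n = len(df)
    cols = [np.ones(n)]
    cols.extend(parse_term(t, df) for t in terms)
    return np.column_stack(cols)


def required_mains(term: str) -> tuple[str, ...]:
    """Main effects that must accompany a term under marginality."""
    if term.startswith("I(") and term.endswith("^2)"):
        return (term[2:-3],)
    if ":" in term:
        a, b = term.split(":", 1)
        return (a, b)
    return ()


def term_metrics(term: str) -> tuple[str, ...]:
    """Underlying metric column(s) a term involves (for collinearity rules)."""
    if term.startswith("I(") and term.endswith("^2)"):
        return (term[2:-3],)
    if ":" in term:
        return tuple(term.split(":", 1))
    return (term,)
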