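"""Shared fixtures and independent oracles.

The oracles here recompute expected values by definition (exact rational
hypergeometric enumeration, hand step-up FDR) and never call the code paths
they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from gutenrich.arraydiff import ExpressionMatrix
from gutenrich.ontology import Ontology, load_obo

DIAMOND_OBO = """\
format-version: 1.2

[Term]
id: GO:000000A
name: apex
namespace: biological_process

[Term]
id: GO:000000B
name: left
namespace: biological_process
is_a: GO:000000A

[Term]
id: GO:000000C
name: right
namespace: biological_process
is_a: GO:000000A

[Term]
id: GO:000000D
name: bottom
namespace: biological_process
is_a: GO:000000B
is_a: GO:000000C
"""

A, B, C, D = "GO:000000A", "GO:000000B", "GO:000000C", "GO:000000D"


@pytest.fixture()
def diamond(tmp_path) -> Ontology:
    """A is_a diamond: D -> {B, C} -> A."""
    path = tmp_path / "diamond.obo"
    path.write_text(DIAMOND_OBO)
    return load_obo(path)


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact rational hypergeometric enumeration."""
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return 1.0
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    observed = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for x in range(lo, hi + 1):
        p = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        if p <= observed:
            total += p
    return float(min(total, Fraction(1)))


def bh_oracle(pvals) -> np.ndarray:
    """Step-up BH by the textbook formula q(i) = min_{j>=i} p(j) * m / j."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def toy_matrix(values: np.ndarray, conditions, times, log2: bool = True) -> ExpressionMatrix:
    """Wrap a raw array into an ExpressionMatrix with minimal metadata."""
    n = values.shape[1]
    samples = [f"s{i}" for i in range(n)]
    frame = pd.DataFrame(values, index=[f"p{i}" for i in range(values.shape[0])],
                         columns=samples)
    meta = pd.DataFrame({
        "sample_id": samples,
        "condition": list(conditions),
        "time_h": list(times),
        "dye": ["Cy3" if i % 2 == 0 else "Cy5" for i in range(n)],
        "replicate": [i // 2 + 1 for i in range(n)],
    }).set_index("sample_id")
    return ExpressionMatrix(values=frame, samples=meta, log2=log2)
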