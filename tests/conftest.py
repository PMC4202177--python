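import numpy as np
import pytest

from pathwaybn.expression import ExpressionMatrix

# KGML fixture: three enzyme entries (K00001; K00002; K00003+K00004), one
# compound entry, relation e1->e2 (ECrel, compound C00022) and e2->e3 (PPrel).
THREE_ENTRY_KGML = """<?xml version="1.0"?>
<pathway name="path:ko00010" org="ko" number="00010">
  <entry id="1" name="ko:K00001" type="ortholog"/>
  <entry id="2" name="ko:K00002" type="ortholog"/>
  <entry id="3" name="ko:K00003 ko:K00004" type="ortholog"/>
  <entry id="4" name="cpd:C00022" type="compound"/>
  <relation entry1="1" entry2="2" type="ECrel">
    <subtype name="compound" value="4"/>
  </relation>
  <relation entry1="2" entry2="3" type="PPrel"/>
</pathway>
"""


def make_matrix(values, gene_ids=None, condition_ids=None, mask=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n)]
    condition_ids = condition_ids or [f"c{j}" for j in range(m)]
    if mask is None:
        mask = np.isnan(values)
        values = np.where(mask, 0.0, values)
    return ExpressionMatrix(list(gene_ids), list(condition_ids), values,
                            np.asarray(mask, dtype=bool))


@pytest.fixture
def three_entry_kgml() -> str:
    return THREE_ENTRY_KGML


@pytest.fixture
def random_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    return make_matrix(rng.normal(size=(6, 40)))
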