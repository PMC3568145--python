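import numpy as np
import pandas as pd
import pytest

from oncocis.io import NORMAL, TUMOR, AlterationDataset


def make_dataset(
    n_genes=8,
    n_tumors=10,
    n_normals=4,
    amp_genes=(0,),
    del_genes=(1,),
    null_amp_genes=(),
    null_del_genes=(),
    n_events=3,
    shift=3.0,
    seed=0,
):
    """Small hand-built dataset: ``amp_genes``/``del_genes`` carry +-2 events
    with an expression shift in the event samples; ``null_amp_genes``/
    ``null_del_genes`` carry events without any expression change (they feed
    the internal null); everything else is neutral noise."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i}" for i in range(n_genes)]
    tumors = [f"T{i}" for i in range(n_tumors)]
    normals = [f"N{i}" for i in range(n_normals)]
    expr = rng.normal(7.0, 0.5, size=(n_genes, n_tumors + n_normals))
    cna = np.zeros((n_genes, n_tumors), dtype=np.int8)
    for g in amp_genes:
        cna[g, :n_events] = 2
        expr[g, :n_events] += shift
    for g in del_genes:
        cna[g, :n_events] = -2
        expr[g, :n_events] -= shift
    for g in null_amp_genes:
        cna[g, rng.choice(n_tumors, size=n_events, replace=False)] = 2
    for g in null_del_genes:
        cna[g, rng.choice(n_tumors, size=n_events, replace=False)] = -2
    annotation = pd.Series(
        {**{t: TUMOR for t in tumors}, **{n: NORMAL for n in normals}}
    )
    return AlterationDataset(
        expression=pd.DataFrame(expr, index=genes, columns=tumors + normals),
        cna=pd.DataFrame(cna, index=genes, columns=tumors),
        annotation=annotation,
    )


@pytest.fixture
def toy_dataset():
    return make_dataset()
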