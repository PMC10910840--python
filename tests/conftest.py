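import numpy as np
import pandas as pd
import pytest

from chipqc import GenotypeDataset


def make_dataset(calls, positions=None, chrom="scaffold_1", categories=None,
                 populations=None, coords=None, score=None):
    """Small hand-built dataset helper used across the suite."""
    calls = np.asarray(calls, dtype=np.int8)
    ns, nv = calls.shape
    sample_ids = [f"s{i + 1}" for i in range(ns)]
    if positions is None:
        positions = np.arange(1, nv + 1) * 100
    variants = pd.DataFrame({
        "id": [f"v{j + 1}" for j in range(nv)],
        "chrom": chrom if isinstance(chrom, str) else list(chrom),
        "pos": list(positions),
        "ref": ["A"] * nv,
        "alt": ["G"] * nv,
        "category": categories if categories is not None else ["intron"] * nv,
    })
    if score is not None:
        variants["score"] = score
    meta = None
    if populations is not None:
        meta = pd.DataFrame({"population": list(populations)},
                            index=pd.Index(sample_ids, name="sample_id"))
        if coords is not None:
            meta["lat"] = [coords[p][0] for p in populations]
            meta["lon"] = [coords[p][1] for p in populations]
    return GenotypeDataset(sample_ids=sample_ids, variants=variants,
                           calls=calls, sample_meta=meta)


@pytest.fixture
def dataset_factory():
    return make_dataset
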