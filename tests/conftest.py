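import numpy as np
import pandas as pd
import pytest

from fibroniche.synthetic_data import SyntheticConfig, generate_tissue


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """A small but fully structured tissue core (fast to generate)."""
    return SyntheticConfig(
        seed=4,
        tissue_width=300.0,
        tissue_height=300.0,
        n_lumens=1,
        lumen_radius_range=(40.0, 55.0),
        n_free_cells=250,
        transcripts_per_cell_mean=40.0,
        contamination_rate=0.1,
    )


@pytest.fixture(scope="session")
def small_tissue(small_cfg):
    return generate_tissue(small_cfg)


@pytest.fixture(scope="session")
def typed_cells(small_tissue):
    """Cell table with planted cell types, lineages and niche regions joined."""
    _, cells, truth = small_tissue
    out = cells.copy()
    types = pd.Series(truth.cell_type_truth)
    out["cell_type"] = types.reindex(out["cell_id"]).to_numpy()
    out["lineage"] = out["cell_type"].map(truth.lineage_truth)
    out["niche_region"] = truth.niche_label_cell
    return out


def make_transcripts(x, y, gene="G1", qv=30.0, nucleus=None, probe="gene", sample="s1"):
    """Assemble a minimal transcript table from coordinate arrays."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    n = len(x)

    def rep(v):
        return np.resize(np.atleast_1d(np.asarray(v, dtype=object)), n)

    return pd.DataFrame(
        {
            "x_location": x,
            "y_location": np.resize(np.atleast_1d(np.asarray(y, dtype=float)), n),
            "feature_name": rep(gene),
            "qv": np.resize(np.atleast_1d(np.asarray(qv, dtype=float)), n),
            "probe_class": rep(probe),
            "nucleus_id": pd.array(rep(nucleus), dtype="string"),
            "sample_id": rep(sample),
        }
    )
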