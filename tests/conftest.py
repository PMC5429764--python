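import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import rilqts

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

ENVS = ["E1", "E2"]


def make_map(n_markers, chromosome="1", positions_bp=None, positions_cM=None, prefix="m"):
    """Small marker map on one chromosome."""
    if positions_bp is None:
        positions_bp = [1000 * (i + 1) for i in range(n_markers)]
    table = pd.DataFrame(
        {
            "marker_id": [f"{prefix}{i + 1}" for i in range(n_markers)],
            "chromosome": chromosome,
            "position_bp": positions_bp,
        }
    )
    if positions_cM is not None:
        table["position_cM"] = positions_cM
    return rilqts.MarkerMap(table)


def make_genotypes(codes, gmap=None, line_prefix="L"):
    codes = np.asarray(codes, dtype=float)
    if gmap is None:
        gmap = make_map(codes.shape[1])
    lines = [f"{line_prefix}{i + 1}" for i in range(codes.shape[0])]
    return rilqts.GenotypeMatrix(lines, gmap, codes)


def make_phenotypes(values_by_env, trait="y", line_ids=None, environments=ENVS):
    """values_by_env: mapping environment -> vector of per-line values."""
    rows = []
    for env, vals in values_by_env.items():
        vals = np.asarray(vals, dtype=float)
        ids = line_ids or [f"L{i + 1}" for i in range(len(vals))]
        for l, v in zip(ids, vals):
            rows.append({"line_id": l, "environment": env, "trait": trait, "value": v})
    return rilqts.PhenotypeTable(pd.DataFrame(rows), environments)


def random_ril_codes(rng, n_lines, n_markers):
    """Unlinked +-1 codes (independent fair coins, the RIL marginal)."""
    return rng.choice([-1.0, 1.0], size=(n_lines, n_markers))


@pytest.fixture(scope="session")
def gyd_preset():
    return rilqts.make_truth_preset("GYD")


@pytest.fixture(scope="session")
def gyd_bundle(gyd_preset):
    """138-line GYD preset dataset on a sparse genome (deterministic)."""
    gmap = gyd_preset.build_map(markers_per_chromosome=5)
    cfg = rilqts.SimMapConfig(markers_per_chromosome=5, n_lines=138, seed=101)
    g = rilqts.simulate_ril_genotypes(cfg, gmap, method="mosaic")
    p = rilqts.simulate_phenotypes(g, gyd_preset.truth(ENVS), ENVS, seed=102, trait_name="GYD")
    return rilqts.validate_dataset(g, p)
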