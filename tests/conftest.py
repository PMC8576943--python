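import numpy as np
import pandas as pd
import pytest

from multiregion import simdata, variants


def build_table(variant_specs, sample_meta=None, patient="P1"):
    """Assemble a small VariantTable from terse per-variant specs.

    variant_specs: dict vid -> {"calls": {sample: (depth, alt)}, plus any
    variant-level annotation overrides}.  Unlisted samples get depth 100,
    0 alt reads.  A matched normal "N" (depth 100) is always included
    unless sample_meta says otherwise.
    """
    if sample_meta is None:
        sids = sorted({s for spec in variant_specs.values() for s in spec["calls"]})
        sample_meta = {s: (1.0, "primary") for s in sids}
        sample_meta["N"] = (1.0, "normal")
    samples = pd.DataFrame(
        {
            "purity": [m[0] for m in sample_meta.values()],
            "tissue": [m[1] for m in sample_meta.values()],
        },
        index=pd.Index(list(sample_meta), name="sample_id"),
    )
    defaults = dict(
        chrom="1", ref="A", alt="T", gene="GENE", effect="missense",
        homopolymer=False, strand_bias=False, blacklist=False,
        population_af=0.0, known_somatic=True, census_gene=False,
    )
    vrows, crows = [], []
    for i, (vid, spec) in enumerate(variant_specs.items()):
        row = dict(defaults)
        row.update({k: v for k, v in spec.items() if k != "calls"})
        row.setdefault("pos", (i + 1) * 100)
        row["variant_id"] = vid
        vrows.append(row)
        for sid in samples.index:
            depth, alt = spec["calls"].get(sid, (100, 0))
            crows.append(
                {"variant_id": vid, "sample_id": sid, "depth": depth, "alt_reads": alt}
            )
    vdf = pd.DataFrame(vrows).set_index("variant_id")
    return variants.make_table(patient, samples, vdf, pd.DataFrame(crows))


@pytest.fixture
def simple_table():
    """Two clean variants over three tumor regions (all passing)."""
    return build_table(
        {
            "v1": {"calls": {"A": (100, 50), "B": (100, 48), "C": (100, 52)}},
            "v2": {"calls": {"A": (100, 20), "B": (100, 0), "C": (100, 0)}},
        }
    )


@pytest.fixture
def branched_tumor():
    """Simulated branched tumor: truncal clone + two region-confined subclones."""
    cfg = simdata.SimConfig(
        n_regions=4,
        n_clonal=25,
        tree_splits=[(0, 0.45, (0, 1)), (0, 0.35, (2, 3))],
        n_private=20,
        mu_eff=8.0,
        depth_mean=300.0,
        purity=0.8,
        seed=11,
    )
    return cfg, simdata.simulate_tumor(cfg)


@pytest.fixture
def filtered_branched(branched_tumor):
    _, (_, truth, table) = branched_tumor
    out = variants.recover_variants(variants.apply_filters(table, variants.FilterRules()))
    return truth, out
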