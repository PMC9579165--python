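import warnings

import numpy as np
import pandas as pd
import pytest

import proteoscan as ps


@pytest.fixture(scope="session")
def screen_bundle():
    """One default-scale synthetic screen run through the full pipeline."""
    cfg = ps.ScreenSimConfig(seed=11)
    m, manifest, growth, truth = ps.generate_screen(cfg)
    normed, report = ps.normalize_pipeline(m, manifest)
    ref = ps.build_wt_reference(normed, manifest)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        de = ps.ztest_de(normed, manifest, ref)
    summary = ps.summarize_strains(de, normed, manifest)
    return dict(config=cfg, raw=m, manifest=manifest, growth=growth,
                truth=truth, normed=normed, report=report, ref=ref,
                de=de, summary=summary)


@pytest.fixture(scope="session")
def paired_bundle():
    """Default paired transcriptome/proteome simulation with fold changes."""
    cfg = ps.PairedSimConfig(seed=4)
    tx, prot, truth = ps.generate_paired_omics(cfg)
    fc = ps.build_foldchanges(tx, prot, truth.sample_to_strain)
    return dict(config=cfg, txome=tx, proteome=prot, truth=truth, fc=fc)


@pytest.fixture(scope="session")
def codon_bundle(paired_bundle):
    """Synthetic ORFs with a planted optimality signal (bias 1) plus profiles."""
    table = ps.default_codon_table()
    truth = paired_bundle["truth"]
    orfs = ps.generate_orfs(truth, table, bias=1.0, seed=9)
    profiles = ps.codon_usage(orfs)
    return dict(table=table, orfs=orfs, profiles=profiles, truth=truth)


@pytest.fixture()
def tiny_manifest():
    """One conforming 8+1+1 run."""
    return ps.build_layout(8, 1)
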