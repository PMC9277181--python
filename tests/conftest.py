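"""Shared fixtures: the default synthetic study corpus, its drug cohorts,
and one fitted end-to-end pipeline reused by the slower tests."""

from __future__ import annotations

import pytest

from dilic.external_cohorts import Source, build_lexicon, load_cohort
from dilic.pipeline import PipelineConfig, evaluate_holdout
from dilic.synthetic_corpus import SynthConfig, generate_cohorts, generate_corpus


@pytest.fixture(scope="session")
def default_synth():
    """Default synthetic corpus: 500+500 docs, 10 planted patterns,
    enrichment 8, seed 42."""
    cfg = SynthConfig()
    docs, truth = generate_corpus(cfg)
    return docs, truth


@pytest.fixture(scope="session")
def default_lexicon(default_synth, tmp_path_factory):
    docs, truth = default_synth
    d = tmp_path_factory.mktemp("cohorts")
    fda, sider = generate_cohorts(truth.config, truth)
    fda.to_csv(d / "fda.tsv", sep="\t", index=False)
    sider.to_csv(d / "sider.tsv", sep="\t", index=False)
    records = load_cohort(d / "fda.tsv", Source.FDA) + load_cohort(d / "sider.tsv", Source.SIDER)
    return build_lexicon(records)


@pytest.fixture(scope="session")
def default_holdout(default_synth, default_lexicon):
    """One 80/20 train/test run of the full default pipeline."""
    docs, _ = default_synth
    return evaluate_holdout(docs, default_lexicon, PipelineConfig(), split_seed=0)
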