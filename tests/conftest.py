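import numpy as np
import pandas as pd
import pytest

from cnaps import (ClassifiedSegment, ExpressionMatrix, GeneModel,
                   PipelineConfig, SegmentRecord, classify_segments)

#: representative log2 amplitude per state, used to build state sequences
STATE_MEANS = {"HOMDEL": -2.0, "HEMIDEL": -0.5, "NEUTRAL": 0.0,
               "GAIN": 0.5, "AMP": 1.0}


def make_segment(start, end, seg_mean, sample="S1", chrom="1", probes=None,
                 cancer_type="CT"):
    return SegmentRecord(sample_id=sample, cancer_type=cancer_type,
                         chrom=chrom, start=start, end=end,
                         seg_mean=seg_mean, num_probes=probes)


def segments_from_states(states, seg_len=50_000, start=1, **kw):
    """Contiguous classified segments realizing a state sequence."""
    records = []
    pos = start
    for s in states:
        records.append(make_segment(pos, pos + seg_len - 1,
                                    STATE_MEANS[s], **kw))
        pos += seg_len
    return classify_segments(records)


def make_gene(gene_id, start, end, strand="+", biotype="coding", chrom="1"):
    return GeneModel(gene_id=gene_id, gene_name=gene_id, chrom=chrom,
                     start=start, end=end, strand=strand, biotype=biotype)


@pytest.fixture
def cfg():
    return PipelineConfig()


@pytest.fixture
def two_gene_layout():
    """Plus-strand coding genes A and B with a 300 kb intergenic region."""
    return [make_gene("A", 100_000, 200_000),
            make_gene("B", 500_000, 600_000)]


def make_expression(data: dict, labels: dict) -> ExpressionMatrix:
    """data: gene -> {sample: linear value}; labels: sample -> cancer type."""
    values = pd.DataFrame(data).T
    return ExpressionMatrix(values, pd.Series(labels))


@pytest.fixture(scope="session")
def default_cohort():
    """One small deterministic cohort shared by the slower tests."""
    from cnaps import SimConfig, simulate_cohort
    return simulate_cohort(SimConfig(
        seed=7, cancer_types=("CA", "CB"), n_samples=20,
        chrom_lengths={"1": 80_000_000, "2": 80_000_000},
        n_genes_per_chrom=40, n_ps_pairs=2))
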