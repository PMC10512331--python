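import numpy as np
import pytest

from coexhub.data_model import CountMatrix, GeneAnnotation, SampleInfo


def make_samples(n_timepoints=1, reps=2, timepoints=None, strain="WT"):
    """Balanced treatment/control design helper."""
    tps = timepoints or [6.0 * (i + 1) for i in range(n_timepoints)]
    samples = []
    for tp in tps:
        for cond in ("treatment", "control"):
            for r in range(1, reps + 1):
                samples.append(SampleInfo(
                    sample_id=f"{cond[:4]}_{int(tp)}h_r{r}",
                    condition=cond, strain=strain,
                    timepoint_h=tp, replicate=r))
    return samples


def make_counts(counts, samples=None, gene_ids=None):
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    if samples is None:
        samples = [SampleInfo(f"s{j}", "treatment" if j % 2 == 0 else "control",
                              "WT", 6.0, j // 2 + 1)
                   for j in range(n_samples)]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    return CountMatrix(gene_ids=gene_ids, samples=samples, counts=counts)


@pytest.fixture
def toy_annotation():
    return {
        "g0": GeneAnnotation("g0", 0.9, "defense mechanisms", "chitinase", True),
        "g1": GeneAnnotation("g1", 0.49, "function unknown", ""),
        "g2": GeneAnnotation("g2", 0.50, "signal transduction mechanisms", "kinase"),
        "g3": GeneAnnotation("g3", 0.0, "unassigned", ""),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
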