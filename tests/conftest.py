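import numpy as np
import pytest

import vaemarker as vm


@pytest.fixture(scope="session")
def sim300():
    """Small synthetic cohort: 300 genes, 30 DE of which 10 biomarkers."""
    cfg = vm.SimulationConfig(n_genes=300, n_de=30, n_biomarkers=10, seed=1)
    counts, labels, truth = vm.simulate_counts(cfg)
    return counts, labels, truth


@pytest.fixture(scope="session")
def trained_toy(sim300):
    """A trained model on 40 genes (10 planted biomarkers + 30 others)."""
    counts, labels, truth = sim300
    genes = list(truth.biomarker_gene_ids) + [
        g for g in counts.gene_ids if g not in set(truth.de_gene_ids)][:30]
    sub = counts.subset_genes(genes)
    train_ids, test_ids = vm.vaejmlp.stratified_split(labels, 0.2, 0)
    scaled = vm.minmax_scale(sub, train_ids, log2=True)
    sched = vm.TrainingSchedule(total_epochs=120, vae_only_epochs=30,
                                mlp_only_epochs=30, joint_epochs=60,
                                batch_size=64, seed=0)
    model = vm.train(scaled, labels, vm.ArchitectureSpec.scaled(len(genes)),
                     sched, split=(train_ids, test_ids))
    return model, scaled, labels, truth
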