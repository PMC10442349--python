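import numpy as np
import pandas as pd
import pytest

from brstnet.core_io import CountMatrix, Section, SpotTable
from brstnet.evaluation import evaluate
from brstnet.modeling import LossSpec
from brstnet.preprocessing import preprocess_dataset
from brstnet.synthetic import SynthConfig, generate_sections
from brstnet.training import TrainConfig, run_experiment

# study conditions of the desk-scale end-to-end benchmark: 6 patients x 1
# section x 200 spots, 64 px patches, 20 signal + 50 noise genes
BENCH_SEED = 1
BENCH_CONFIG = dict(
    n_patients=6,
    sections_per_patient=1,
    spots_per_section=200,
    image_size=512,
    patch_size=64,
    n_signal_genes=20,
    n_noise_genes=50,
    signal_strength=0.9,
    count_scale=2000.0,
)
BENCH_TRAIN = dict(
    max_epochs=30,
    lr=0.01,
    early_stopping_patience=15,
    scheduler_patience=8,
)


def make_section(
    image: np.ndarray,
    coords: list[tuple[str, int, int]],
    counts: np.ndarray,
    gene_ids: list[str] | None = None,
    patient: str = "P0",
    section: str = "S0",
) -> Section:
    spot_ids = [c[0] for c in coords]
    gene_ids = gene_ids or [f"g{j}" for j in range(counts.shape[1])]
    return Section(
        patient_id=patient,
        section_id=section,
        image=image,
        spots=SpotTable(
            pd.DataFrame(coords, columns=["spot_id", "x", "y"])
        ),
        counts=CountMatrix(
            pd.DataFrame(counts, index=spot_ids, columns=gene_ids)
        ),
    )


def run_benchmark(seed: int = BENCH_SEED):
    """Full synthetic pipeline at the desk-scale study conditions."""
    cfg = SynthConfig(seed=seed, **BENCH_CONFIG)
    ds = generate_sections(cfg)
    pre = preprocess_dataset(
        ds.sections, patch_size=cfg.patch_size, n_main_genes=cfg.n_signal_genes
    )
    result = run_experiment(
        pre,
        test_patient="P000",
        backbone="tiny_cnn",
        n_folds=5,
        train_config=TrainConfig(seed=seed, **BENCH_TRAIN),
        loss_spec=LossSpec(lambda_aux=40.0),
        seed=seed,
    )
    report = evaluate(result.predictions, result.targets)
    return cfg, pre, result, report


@pytest.fixture(scope="session")
def benchmark_run():
    """One shared end-to-end run; ~3 min on one CPU."""
    return run_benchmark()


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SynthConfig(
        n_patients=2,
        sections_per_patient=1,
        spots_per_section=40,
        image_size=256,
        patch_size=32,
        n_signal_genes=5,
        n_noise_genes=10,
        count_scale=2000.0,
        seed=11,
    )
    return generate_sections(cfg)
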