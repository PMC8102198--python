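import pandas as pd
import pytest

from lncforge.genomic_model import ExpressionMatrix, PipelineParams
from lncforge.pipeline import RunConfig, run_pipeline
from lncforge.synthetic_data import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def params():
    return PipelineParams()


def make_expr(values: dict, samples: list[str], groups: dict[str, str]) -> ExpressionMatrix:
    """Small expression matrix from a gene -> per-sample TPM list mapping."""
    df = pd.DataFrame.from_dict(values, orient="index", columns=samples, dtype=float)
    return ExpressionMatrix(values=df, groups=groups)


def run_on_dataset(paths: dict, out_dir) -> None:
    config = RunConfig(
        candidates_gtf=paths["candidates_gtf"],
        coding_gtf=paths["coding_gtf"],
        scores_tsv=paths["scores_tsv"],
        expr_tsv=paths["expr_tsv"],
        groups_tsv=paths["groups_tsv"],
        annotated_gtf=paths["annotated_gtf"],
        bcell_gtf=paths["bcell_gtf"],
        seg_manifest=paths["seg_manifest"],
        out_dir=str(out_dir),
    )
    return run_pipeline(config)


@pytest.fixture(scope="session")
def noiseless_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("noiseless_ds")
    cfg = SynthConfig(seed=1).noiseless()
    paths, truth = generate_dataset(cfg, out)
    return cfg, paths, truth


@pytest.fixture(scope="session")
def noiseless_run(noiseless_dataset, tmp_path_factory):
    _, paths, truth = noiseless_dataset
    out = tmp_path_factory.mktemp("noiseless_run")
    report = run_on_dataset(paths, out)
    return out, report, truth


@pytest.fixture(scope="session")
def noisy_run(tmp_path_factory):
    ds = tmp_path_factory.mktemp("noisy_ds")
    cfg = SynthConfig(seed=3)  # default noise level
    paths, truth = generate_dataset(cfg, ds)
    out = tmp_path_factory.mktemp("noisy_run")
    report = run_on_dataset(paths, out)
    return out, report, truth


def label_sets(run_dir):
    """Recovered label sets from the stage TSVs of a pipeline run."""
    cat = pd.read_csv(run_dir / "catalog.tsv", sep="\t", index_col=0)
    coh = pd.read_csv(run_dir / "cohort_deregulation.tsv", sep="\t", index_col=0)
    out = {
        "novel_pass": set(cat.index[cat["is_novel_lncrna"]]),
        "dereg_up": set(coh.index[coh["cohort_label"] == "up"]),
        "dereg_down": set(coh.index[coh["cohort_label"] == "down"]),
        "mm_specific": set(),
        "de_novo": set(),
    }
    dyn_path = run_dir / "dynamics.tsv"
    if dyn_path.exists():
        dyn = pd.read_csv(dyn_path, sep="\t", index_col=0)
        out["mm_specific"] = set(dyn.index[dyn["mm_specific"]])
    dn_path = run_dir / "de_novo.tsv"
    if dn_path.exists():
        dn = pd.read_csv(dn_path, sep="\t", index_col=0)
        out["de_novo"] = set(dn.index[dn["de_novo"]])
    return out


def f1(got: set, want: set) -> float:
    if not got and not want:
        return 1.0
    tp = len(got & want)
    return 2.0 * tp / (len(got) + len(want))
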