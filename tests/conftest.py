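from pathlib import Path

import numpy as np
import pytest

from hubdrug import ModuleSpec, SyntheticConfig

SYNTH_YAML = """\
n_genes: 80
n_samples: 200
noise_sd: 0.3
hub_variance_scale: 4.0
sensitivity_noise_sd: 0.4
modules:
  - {size: 6, hub_loading: 0.95, member_loading: 0.7}
drugs: [d1, d2, d3]
drug_intercepts: {d1: 1.0, d2: 2.5, d3: 3.0}
drug_effects:
  d1: [0.6]
  d2: [0.4]
  d3: [-0.5]
"""


@pytest.fixture
def run_cli_chain():
    """Run the full CLI stage chain into a fresh directory and return it."""
    from click.testing import CliRunner

    from hubdrug.cli import main as cli_main

    def _run(tmp_path: Path, tag: str) -> Path:
        out = tmp_path / tag
        out.mkdir()
        cfg = tmp_path / "synth.yaml"
        if not cfg.exists():
            cfg.write_text(SYNTH_YAML)
        runner = CliRunner()
        steps = [
            ["simulate", "--config", str(cfg), "--seed", "7", "--out-dir", str(out)],
            ["network", "--expression", f"{out}/expression.tsv", "--percentile", "0",
             "--out-dir", str(out)],
            ["hubs", "--network", f"{out}/network_edges.tsv", "-B", "2000",
             "--seed", "7", "--out", f"{out}/hubs.tsv"],
            ["fit", "--expression", f"{out}/expression.tsv",
             "--sensitivity", f"{out}/sensitivity_aa.tsv",
             "--hubs", f"{out}/hubs.tsv", "--out", f"{out}/model.json"],
            ["cv", "--expression", f"{out}/expression.tsv",
             "--sensitivity", f"{out}/sensitivity_aa.tsv",
             "--hubs", f"{out}/hubs.tsv", "--k", "5", "--seed", "7",
             "--out", f"{out}/cv.tsv"],
            ["predict", "--model", f"{out}/model.json",
             "--expression", f"{out}/expression.tsv", "--out", f"{out}/predictions.tsv"],
            ["evaluate", "--predictions", f"{out}/predictions.tsv",
             "--sensitivity", f"{out}/sensitivity_aa.tsv", "--out", f"{out}/report.tsv"],
            ["evaluate", "--predictions", f"{out}/predictions.tsv",
             "--sensitivity", f"{out}/sensitivity_lnic50.tsv",
             "--orientation", "inverse", "--out", f"{out}/report_inverse.tsv"],
        ]
        for args in steps:
            result = runner.invoke(cli_main, args, catch_exceptions=False)
            assert result.exit_code == 0, f"{args}: {result.output}"
        return out

    return _run


@pytest.fixture
def make_config():
    """Factory for compact synthetic configurations.

    Defaults to a single drug with a unit effect on the first planted hub;
    pass ``shared_beta`` to give every drug the same effect vector.
    """

    def _make(
        n_genes=30,
        n_samples=100,
        modules=((5, 0.95, 0.7),),
        drugs=("drugA",),
        intercepts=None,
        effects=None,
        shared_beta=None,
        **kwargs,
    ):
        modules = [ModuleSpec(size=s, hub_loading=h, member_loading=m)
                   for s, h, m in modules]
        drugs = list(drugs)
        if intercepts is None:
            intercepts = {d: 1.0 + i for i, d in enumerate(drugs)}
        if effects is None:
            if shared_beta is None:
                base = np.zeros(len(modules))
                base[0] = 1.0
                shared_beta = base
            effects = {d: np.asarray(shared_beta, dtype=float) for d in drugs}
        return SyntheticConfig(
            n_genes=n_genes,
            n_samples=n_samples,
            modules=modules,
            drugs=drugs,
            drug_intercepts=intercepts,
            drug_effects=effects,
            **kwargs,
        )

    return _make
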