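import json
import shutil
import subprocess

import pandas as pd
import pytest

from mirnet.pipeline import load_config, run_all
from mirnet.synthetic import make_design


@pytest.fixture(scope="session")
def design12() -> pd.DataFrame:
    """The core 6-group, 12-sample dox-induced design."""
    return make_design(n_reps=2, include_no_dox=False)


@pytest.fixture(scope="session")
def e2e(tmp_path_factory):
    """One full default pipeline run shared by the end-to-end tests."""
    out = tmp_path_factory.mktemp("e2e")
    report = run_all(load_config(seed=1), out)
    return {"out": out, "report": report}


def has_rscript() -> bool:
    return shutil.which("Rscript") is not None


def rscript(code: str) -> str:
    res = subprocess.run(
        ["Rscript", "-e", code], capture_output=True, text=True, timeout=300
    )
    if res.returncode != 0:
        raise RuntimeError(f"Rscript failed: {res.stderr[-2000:]}")
    return res.stdout
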