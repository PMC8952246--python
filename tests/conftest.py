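import pathlib

import numpy as np
import pytest

from gxp import fixtures
from gxp.tables_io import (
    AnnotationColumn,
    ExpressionMatrix,
    InfoTable,
    parse_sample_name,
)


@pytest.fixture()
def datadir_golden():
    """Golden-file helper: returns the frozen file content, freezing the
    supplied content on the very first run (the frozen copy is committed)."""
    data = pathlib.Path(__file__).parent / "data"

    def _get(name: str, content: str) -> str:
        path = data / name
        if not path.exists():
            data.mkdir(exist_ok=True)
            path.write_text(content)
        return path.read_text()

    return _get


@pytest.fixture(scope="session")
def default_bundle():
    return fixtures.generate(fixtures.FixtureDesign(seed=7))


@pytest.fixture(scope="session")
def ora_bundle():
    return fixtures.generate(fixtures.ora_design(seed=7))


@pytest.fixture()
def tiny_expr():
    """3 entities x 4 samples, 2 x-levels x 2 replicates, no group factor."""
    names = ["ctrl.1", "ctrl.2", "cold.1", "cold.2"]
    return ExpressionMatrix(
        entity_ids=["g1", "g2", "g3"],
        samples=[parse_sample_name(n) for n in names],
        values=np.array(
            [
                [4.0, 6.0, 10.0, 14.0],
                [1.0, 1.0, 2.0, 2.0],
                [7.0, 7.0, 7.0, 7.0],
            ]
        ),
        unit="TPM",
    )


@pytest.fixture()
def grouped_expr():
    """1 group factor (a/b), 2 x-levels, 2 replicates."""
    names = [f"{g}.{x}.{r}" for g in ("a", "b") for x in ("ctrl", "cold") for r in (1, 2)]
    rng = np.random.default_rng(0)
    return ExpressionMatrix(
        entity_ids=["g1", "g2"],
        samples=[parse_sample_name(n) for n in names],
        values=rng.uniform(1, 10, size=(2, 8)),
        unit="TPM",
    )


@pytest.fixture()
def tiny_info():
    return InfoTable(
        entity_ids=["g1", "g2", "g3"],
        columns={
            "description": AnnotationColumn(
                name="description",
                kind="text",
                cells=["chalcone synthase like", "unknown protein", "kinase"],
            ),
            "bin": AnnotationColumn(
                name="bin",
                kind="categorical",
                cells=["1.1,9.1", "1.1", ""],
                multivalue_delimiter=",",
            ),
            "log2FC": AnnotationColumn(
                name="log2FC", kind="numeric", cells=[-2.0, 0.5, None]
            ),
        },
    )
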