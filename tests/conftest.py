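import numpy as np
import pytest

from rotagsa import ExpressionData, GeneSet, GeneSetCollection, two_group_design


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_expression(rng):
    """40 genes x 8 samples of independent noise, genes G000..G039."""
    q, n = 40, 8
    values = rng.standard_normal((q, n))
    return ExpressionData(
        values=values,
        gene_ids=tuple(f"G{i:03d}" for i in range(q)),
        sample_ids=tuple(f"S{i}" for i in range(n)),
    )


@pytest.fixture
def toy_design():
    return two_group_design(4)


@pytest.fixture
def toy_collection():
    return GeneSetCollection(
        (
            GeneSet("first_ten", tuple(f"G{i:03d}" for i in range(10)), "toy"),
            GeneSet("mixed", tuple(f"G{i:03d}" for i in range(5, 25)), "toy"),
        )
    )


@pytest.fixture
def toy_files(tmp_path, toy_expression, toy_collection):
    """Expression TSV + design TSV + GMT on disk for io/cli tests."""
    expr_path = tmp_path / "expr.tsv"
    toy_expression.to_frame().to_csv(expr_path, sep="\t")
    design_path = tmp_path / "design.tsv"
    with design_path.open("w") as fh:
        fh.write("sample\tintercept\tgroup\n")
        for i, s in enumerate(toy_expression.sample_ids):
            fh.write(f"{s}\t1\t{int(i >= 4)}\n")
    gmt_path = tmp_path / "sets.gmt"
    with gmt_path.open("w") as fh:
        for s in toy_collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")
    return {"expr": expr_path, "design": design_path, "gmt": gmt_path}
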