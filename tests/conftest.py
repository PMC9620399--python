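import numpy as np
import pytest

from rnaweave import (
    HelixParams,
    build_strand_model,
    builtin_mesh,
    embed_design,
    route,
    spanning_tree,
)


@pytest.fixture(scope="session")
def params():
    return HelixParams()


@pytest.fixture(scope="session")
def tetra_mesh():
    return builtin_mesh("tetrahedron")


@pytest.fixture(scope="session")
def tetra_plan(tetra_mesh):
    return route(tetra_mesh, spanning_tree(tetra_mesh))


@pytest.fixture(scope="session")
def tetra_embedded(tetra_mesh, tetra_plan):
    return embed_design(tetra_mesh, tetra_plan, seed=1)


@pytest.fixture(scope="session")
def tetra_strand(tetra_embedded):
    return build_strand_model(tetra_embedded)


@pytest.fixture(scope="session")
def single_edge_mesh():
    from rnaweave import Mesh

    return Mesh(
        vertices=np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]]),
        edges=[(0, 1)],
        name="single_edge",
    )


@pytest.fixture(scope="session")
def path3_mesh():
    """Path graph on 4 vertices (already a tree)."""
    from rnaweave import Mesh

    return Mesh(
        vertices=np.array(
            [[0.0, 0.0, 0.0], [8.0, 0.0, 0.0], [14.0, 5.0, 0.0], [20.0, 5.0, 4.0]]
        ),
        edges=[(0, 1), (1, 2), (2, 3)],
        name="path3",
    )
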