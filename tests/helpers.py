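import numpy as np

from bnbmla.data_model import DiscreteDataset, VariableMeta


def make_dataset(columns: dict, targets=(), kinds=None) -> DiscreteDataset:
    """Assemble a complete DiscreteDataset from dense code columns."""
    kinds = kinds or {}
    variables, cols = [], []
    for name, col in columns.items():
        col = np.asarray(col, dtype=np.int16)
        arity = int(col.max()) + 1
        role = "target" if name in targets else "predictor"
        kind = kinds.get(name, "phenotype" if role == "target" else "genotype")
        variables.append(
            VariableMeta(name, arity, role=role, kind=kind,
                         levels=tuple(range(arity)))
        )
        cols.append(col)
    return DiscreteDataset(variables, np.column_stack(cols))


def sequential_predictive_log_prob(seq, arity: int) -> float:
    """Independent oracle for the uniform-Dirichlet marginal likelihood.

    The closed-form family score with all hyperparameters 1 equals the
    product of sequential predictive probabilities
    (count_so_far(x_i) + 1) / (i + arity).
    """
    import math

    counts = [0] * arity
    log_p = 0.0
    for i, x in enumerate(seq):
        log_p += math.log((counts[x] + 1) / (i + arity))
        counts[x] += 1
    return log_p


def random_dag_adjacency(rng: np.random.Generator, n: int, p: float = 0.35):
    """Random DAG: edges only from earlier to later in a random order."""
    order = rng.permutation(n)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                adj[order[i], order[j]] = True
    return adj
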