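import numpy as np
import pytest

from brainvqc import cohort as co
from brainvqc import quantum as q


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size synthetic cohort under the default demographic table."""
    return co.generate_cohort(seed=20240)


@pytest.fixture(scope="session")
def small_cohort():
    """~120-subject cohort for fast pipeline tests (default noise)."""
    return co.generate_cohort(co.scaled_demographics(120), co.default_effects(), seed=77)


def dense_unitary(spec: q.CircuitSpec, angles) -> np.ndarray:
    """Brute-force 2^n x 2^n unitary of a circuit via Kronecker products.

    Independent of the simulator's axis-contraction fast path; usable only
    for small n.
    """
    n = spec.n_qubits
    dim = 1 << n
    U = np.eye(dim, dtype=complex)
    eye2 = np.eye(2, dtype=complex)
    for g in spec.gates:
        if g.kind == "CNOT":
            M = np.zeros((dim, dim), dtype=complex)
            cbit = 1 << (n - 1 - g.control)
            tbit = 1 << (n - 1 - g.target)
            for i in range(dim):
                j = i ^ tbit if i & cbit else i
                M[j, i] = 1.0
        else:
            theta = g.angle if g.angle is not None else angles[g.slot]
            mats = [eye2] * n
            mats[g.target] = q.rotation_matrix(g.kind, theta)
            M = mats[0]
            for m in mats[1:]:
                M = np.kron(M, m)
        U = M @ U
    return U


def random_circuit(rng: np.random.Generator, n_qubits: int, n_gates: int) -> q.CircuitSpec:
    """A random trainable circuit over the RX/RY/RZ/CNOT gate set."""
    gates = []
    slot = 0
    for _ in range(n_gates):
        kind = rng.choice(["RX", "RY", "RZ", "CNOT"])
        target = int(rng.integers(n_qubits))
        if kind == "CNOT":
            if n_qubits == 1:
                continue
            control = int(rng.choice([x for x in range(n_qubits) if x != target]))
            gates.append(q.GateOp("CNOT", target, control=control))
        else:
            gates.append(q.GateOp(kind, target, slot=slot, trainable=True))
            slot += 1
    return q.CircuitSpec(n_qubits, tuple(gates))
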