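"""Built-in reference checks.

Published point estimates for layer-2/3 pyramidal-cell recurrent
synapses (N = 6 release sites, first-pulse failure rate 10.6%,
double-failure rate 6.2% at a 20 ms interval, fitted optimum
k1 = 5.21 /s and p_v = 0.999) provide a compact worked example whose
derived quantities the package can recompute exactly.  Each check
re-runs the relevant analysis from its printed inputs and compares the
result with the printed value.
"""

from __future__ import annotations

import numpy as np

from stpkit.calcium import ca_cooperativity_ratio
from stpkit.failures import pr_from_failure, predict_joint
from stpkit.pool import steady_state_occupancy

__all__ = ["reference_checks"]

# Printed inputs for the reference synapse.
N_SITES = 6
P_F1 = 0.106          # first-pulse failure rate
P_F1F2 = 0.062        # double-failure rate
ISI = 0.02            # s
K1_OPT = 5.21         # /s, fitted optimum
PV_OPT = 0.999        # fitted optimum
BASE_OCC = 0.3        # resting site occupancy
REFILL_SUM = 23.0     # /s, k1 + b1 from paired-pulse recovery
CA_LO, CA_HI = 1.3, 2.5   # mM external calcium step
K_CA, K_MG, MG = 1.1, 3.0, 1.0  # mM


def reference_checks(rel_tol: float = 5e-3) -> dict[str, dict]:
    """Recompute the reference quantities and compare with the printed
    values.  Returns {name: {computed, reference, units, ok}}."""
    checks: dict[str, dict] = {}

    def add(name: str, computed: float, reference: float, units: str) -> None:
        ok = abs(computed - reference) <= rel_tol * abs(reference)
        checks[name] = {"computed": float(computed), "reference": reference,
                        "units": units, "ok": bool(ok)}

    p_r = pr_from_failure(P_F1, N_SITES)
    add("release_probability", round(p_r, 3), 0.312, "")

    k1_base = BASE_OCC * REFILL_SUM
    b1_base = REFILL_SUM - k1_base
    add("baseline_k1", k1_base, 6.9, "/s")
    add("baseline_b1", b1_base, 16.1, "/s")
    add("baseline_occupancy", steady_state_occupancy(k1_base, b1_base), 0.3, "")

    p_occ = p_r / PV_OPT
    p11, p10, p01, p00 = predict_joint(K1_OPT, PV_OPT, N_SITES, p_occ, ISI)
    add("joint_P11", 100 * p11, 41.5, "%")
    add("joint_P10", 100 * p10, 47.9, "%")
    add("joint_P01", 100 * p01, 4.93, "%")
    add("joint_P00", 100 * p00, 5.67, "%")

    fold = ca_cooperativity_ratio(CA_LO, CA_HI, K_CA, K_MG, MG)
    add("external_ca_fold_change", fold, 3.24, "fold")
    return checks
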