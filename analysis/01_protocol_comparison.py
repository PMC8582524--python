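#!/usr/bin/env python
"""Simulate the five treatment protocols on the reference mixed tumor.

Starting from 180 mm^3 sensitive + 20 mm^3 resistant tumor at the shipped
typical parameters, runs control, positive control, continuous dosing
(MTD), classic adaptive therapy (AT1) and reachability-based adaptive
therapy (AT2, restore-index rule), and tabulates failure times, switch
times and per-cycle records.  Writes results/protocol_outcomes.csv and one
trajectory CSV per protocol.
"""

from pathlib import Path

import pandas as pd

from reachat.io import write_trajectory
from reachat.protocols import PROTOCOL_KINDS, ProtocolSpec, run_protocol
from reachat.tumor_model import TumorState, default_params

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    params = default_params()
    init = TumorState(0.0, 180.0, 20.0)
    rows = []
    cycle_rows = []
    for kind in PROTOCOL_KINDS:
        spec = ProtocolSpec(kind=kind, at2_rule="restore_index")
        out = run_protocol(params, init, spec)
        rows.append(
            {
                "kind": kind,
                "failure_time": out.failure_time,
                "censored": out.censored,
                "switch_time": out.switch_time,
                "n_cycles": len(out.cycles),
            }
        )
        for c in out.cycles:
            cycle_rows.append({"kind": kind, **vars(c)})
        write_trajectory(out.trajectory, OUT / f"trajectory_{kind}.csv")
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "protocol_outcomes.csv", index=False, float_format="%.6g")
    pd.DataFrame(cycle_rows).to_csv(OUT / "protocol_cycles.csv", index=False, float_format="%.6g")

    print(df.to_string(index=False))
    t = df.set_index("kind")["failure_time"]
    print(
        f"\nAdaptive cycling gains {t['at1'] - t['mtd']:.1f} days over continuous dosing;"
        f" the restore-index switch adds another {t['at2'] - t['at1']:.1f} days."
    )


if __name__ == "__main__":
    main()
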