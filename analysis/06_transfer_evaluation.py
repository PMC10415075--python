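"""In/out cohort-transfer evaluation of the elicited network.

LOO multi-class AUC on the healthy cohort versus the AUC obtained when the
healthy-cohort discretization and CPTs score the shifted patient cohort
without refitting.  Writes results/transfer.json.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from reguframe.bayesnet import DiscreteNet  # noqa: E402
from reguframe.cohort import read_cohort  # noqa: E402
from reguframe.evaluation import in_out_analysis  # noqa: E402

RESULTS = ROOT / "results"


def main() -> None:
    net = DiscreteNet.load(RESULTS / "net.json")
    dag = {v: list(net.parents[v]) for v in net.nodes}
    healthy = read_cohort(RESULTS / "cohort_healthy.csv")
    patients = read_cohort(RESULTS / "cohort_patients.csv")
    res = in_out_analysis(dag, healthy, patients, target=net.target)
    print(f"healthy-cohort LOO multi-class AUC: {res['train_loo_auc']:.3f}")
    print(f"patient-cohort transfer AUC:        {res['transfer_auc']:.3f}")
    (RESULTS / "transfer.json").write_text(json.dumps(res, indent=2))
    print(f"wrote {RESULTS / 'transfer.json'}")


if __name__ == "__main__":
    main()
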