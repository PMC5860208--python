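"""Cross-validate the predictor on a synthetic corpus, with a null control.

Whole complexes are held out together and the propensity table is rebuilt
inside each training fold, so nothing about a test complex leaks into
training.  A corpus with no compositional difference between interface and
surface (signal "none") should cross-validate near MCC 0 - this is the
negative control that the pipeline does not manufacture signal.

Note: featurising 2 x 20 complexes takes a minute or two.
"""

import tempfile
import warnings
from pathlib import Path

from patchpred.pipeline import build_corpus_matrix
from patchpred.predictor import cross_validate_corpus
from patchpred.synthetic import make_training_corpus

warnings.filterwarnings("ignore")

for signal in ("strong", "none"):
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        make_training_corpus(20, signal, seed=7, out_dir=tmp)
        data = build_corpus_matrix(sorted(tmp.glob("*.pdb")), chain_ids=["A"])
        cv = cross_validate_corpus(data, k=10, seed=1)
    print(f"signal={signal:6s}  {cv.mean}")
print("With planted hydrophobic enrichment the forest recovers the interface")
print("patches; with none, MCC sits near zero as it must.")
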