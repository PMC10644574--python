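"""Bottom-up alignment over a replicate folder tree.

Six runs are written as two subfolders of three technical replicates each.
Replicates are aligned first; every consensus group then travels upward as
one representative feature (mean m/z, RT, area), and the two samples are
aligned against each other. Provenance down to leaf feature ids is kept.
"""
import tempfile

from mapalign.pipeline import JobConfig
from mapalign.scaling import align_recursive
from mapalign.synthetic import SynthConfig, generate_benchmark, write_fixture

cfg = SynthConfig(n_runs=6, n_analytes=40, seed=21)
runs, annotation, _ = generate_benchmark(cfg)
names = [r.name for r in runs]

with tempfile.TemporaryDirectory() as tree:
    write_fixture(runs, annotation, tree, nested_groups=[names[:3], names[3:]])
    result = align_recursive(tree, JobConfig(seed=21))
    sizes = sorted((len(g) for g in result.groups), reverse=True)
    print("top-level consensus groups:", len(result.groups))
    print("largest group sizes (leaf features):", sizes[:5])
    full = sum(1 for g in result.groups if len(g) == len(runs))
    print(f"groups spanning all {len(runs)} runs: {full}")
    example = max(result.groups, key=len)
    print("one full group:", sorted(example))
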