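# Deposited-structure morphing worked examples.
#
# The structure files are NOT shipped; run scripts/fetch_benchmarks.py
# (requires network access to files.rcsb.org) to download them into this
# directory before running scripts/morph_benchmark.py or the
# corresponding acceptance test.
cases:
  - name: pppk_3hsz_to_3ht0
    source: 3hsz.pdb
    target: 3ht0.pdb
    chain: A
    loop: [81, 93]
    expected_initial_rmsd: 11.3
    max_final_rmsd: 1.2
  - name: mope_2vov_to_2vox
    source: 2vov.pdb
    target: 2vox.pdb
    chain: A
    loop: [317, 337]
    expected_initial_rmsd: 3.0
    max_final_rmsd: 0.5
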