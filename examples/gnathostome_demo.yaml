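# Worked example: map PHLPP2 presence/absence across jawed vertebrates.
# `pseudolock run --config examples/gnathostome_demo.yaml` writes a Dollo
# event table with one gain (at the gnathostome root) and four
# independent losses: caecilians, squamates, and twice in turtles.
seed: 42
out_dir: runs/gnathostome_demo
stages:
  dollo:
    tree: builtin:gnathostome_phlpp2
    states: builtin:gnathostome_phlpp2
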