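There are 51 orbitals in the unit cell.
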