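{
  "lfp": "aaee943cca880ca468f67793b84d0dc82a79c0e8495582ceed87cf66a88c8b77",
  "kin": "d0ee923a19b39098dcbff32077d92c09e13d25567633e9915a08ba610bafeaea",
  "kernels": "000f0cddcfc127105d5b0e868939aff5d80464432946320de7f7f637213421ad",
  "n_spikes": 9294
}
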