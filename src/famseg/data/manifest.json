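{
  "table2.tsv": "73ede6889716147a31a66c817ed316e298b1c6d80951f9d68e2cf5c594519ec6",
  "table4.tsv": "36cbb6010f0d646ba7670b769cd831957b02f31d2b841bdd9a776f55dd16629d",
  "tc_genes.txt": "b560fea8fd261ace607936e14c646cc50441c8d66a2cd1a3d2e39462ed77810b"
}
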