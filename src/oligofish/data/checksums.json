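{
  "cohort": "1d4529d741baa1ac419a8fb384e319b919d11ee90196d932490e378e3f302398",
  "concordance_chr9": "386c72143f7eb21cce861b6e7f53afaa8a212a09082309d1e1db4511e53850da",
  "concordance_chr10": "1bccec2604c3e75738393f40e1171d8f6ebb44ab025cbc5e92844a8281d77e9d"
}
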