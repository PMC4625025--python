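>mip_template_synthetic synthetic PIP-like reference backbone
CNYSYVWYGMCNVQVWENHMDEESAWTKFLAHILCFLSWKQRLYHTARDYCPGQEHYKAD
TRFIVQWHTCQMHPSDAYCWTLLVQWAFWVEMPWPWRTDNPAPPLWSPRVLAHESCYFRY
WKTVGGMFNYQPYLSDHSIHKLKPWQNYRWDPDVFMCPLDAVLYVFMVYRGPRHYCVIFE
DLNVCVMKFGAVLMAVNNFHFNHCHHYCLGMSKNYATIHGTNPAQTLKDWRINPATEYKF
WLLMEIREQRFNYFERGEMMDVLFVLTIGRCSNSENPCGQMIPIYFHIFE
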