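Decide whether the text asserts that the patient actually has this condition. Answer with exactly one word: Yes or No.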