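9015bb785f950d599d002ea314202d9638b36e104034c930498f860454b11bc0
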