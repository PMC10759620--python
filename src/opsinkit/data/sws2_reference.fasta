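>SWS2_numbering_scaffold synthetic numbering reference (not a biological sequence)
AQKPGDPDDQQVKFFFDRSLQKRHLCELEHAIDMHQCPARGAGQGMWVDWLAFTSGEPLS
ATNWAPCVTLEFNENLSRYKKQGDHYYLTTTRAACIYDCLNHIIEYGHFSREVNMLCFAI
IEENPMMTVMIDIDLRVLTFMYIGASGHNRKMVACRSGTKYRWYWKAQDLSQTEAYNDCQ
PCRCEVMRCCCGKCEWKTHSWQCQYASCTHINHTVKRFQPWYSLHNCGKSTDAQSFPQTM
FTHNAWWLDASYFSKTFTQDFVVCIHVEPLHEYFMNLEVLYQWAIVNSGSAAHYADDCFR
DAWPGPEWNCWISSCHPGYEQADMNCELLRRKCPSYSEEPKQGMAHWEKIANAYIGPVTS
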