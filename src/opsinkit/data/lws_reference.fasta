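>LWS_numbering_scaffold synthetic numbering reference (not a biological sequence)
DDSLNPRALDKWMCMDSWYPVIDMKQYGVDHSFQLMWTTMYYDFHNTLYIWNRFNTVVYD
SLQGACYVHKFDVQCFNWYFPAEFKHRLHWPQRHVAHEAYCLTQVCLAETCNAHWHHCSE
LAATALKDPRYEWCDNVVRAKTMEQCQAIGWRQLGVWFFHLGKYIWMHWKSHYRVADCMS
YFETHRGMCQWQVSNWHDNPEDQKLSQVESMACIPEMYDDYFVISCPVHPFEALMCFPIF
AAPDTNGPEHLPDICDFHWIDWNDCCWNQYKWKRTCYTYQLDSLTAHTPRNTTSQGCSIF
ADAIGLNAMPQPAFSPGIWRIGDSPKQNMQSMKGHYECPHCMRALENSTSGPPWQSCGIP
VHLR
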