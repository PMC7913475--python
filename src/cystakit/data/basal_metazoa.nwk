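(Ctenophora:1,(Porifera:1,(Placozoa:1,((Anthozoa:1,(Staurozoa:1,(Cubozoa:1,(Scyphozoa:1,(Hydrozoa:1,(Polypodiozoa:1,Myxozoa:1):1):1):1):1):1):1,Bilateria:1):1):1):1):0;
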