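code,common_name
C8:0,caprylic acid
C14:0,myristic acid
C16:0,palmitic acid
C16:1,palmitoleic acid
C18:0,stearic acid
C18:1,oleic acid
C18:2,linoleic acid
C18:3,linolenic acid
C20:0,arachidic acid
C20:1,eicosenoic acid
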