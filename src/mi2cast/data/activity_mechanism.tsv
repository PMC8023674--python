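# Bijective mapping between a source-entity molecular activity (GO MF) and
# the equivalent direct-interaction mechanism term (PSI-MI "direct
# interaction" branch).  Extensible; bijectivity is enforced at load.
activity	mechanism
go:0016301	mi:0217
go:0016791	mi:0203
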